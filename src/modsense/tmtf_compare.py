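"""Quantitative comparison of model and human TMTFs.

Human reference TMTFs (per condition, per subject) are averaged across
subjects after linear interpolation along the log-scaled AM rate; model
TMTFs are averaged across the selected models the same way.  Three pooled
indices quantify the match over all conditions x rates:

* pattern similarity — Pearson correlation of the pooled threshold vectors
  (shape similarity, insensitive to offsets);
* discrepancy — RMS deviation in dB (absolute mismatch);
* net difference — mean signed deviation in dB (positive: the model is less
  sensitive than humans).

The exact identity discrepancy^2 = net_difference^2 + var(signed
differences) links the three.  A per-layer correlation of recognition
accuracy with each index (Bonferroni-corrected over layers) quantifies
whether better-recognizing models are more human-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "HumanReference",
    "SimilarityReport",
    "load_reference_csv",
    "average_reference",
    "average_tmtfs",
    "pool_conditions",
    "pattern_similarity",
    "discrepancy",
    "net_difference",
    "compare_tmtfs",
    "accuracy_similarity_correlation",
]


@dataclass
class HumanReference:
    """Per-condition, per-subject reference TMTFs.

    ``table`` columns: condition, subject, rate_hz, threshold_db.
    """

    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        required = {"condition", "subject", "rate_hz", "threshold_db"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table missing columns {sorted(missing)}")
        if (self.table["rate_hz"] <= 0).any():
            raise ValueError("reference AM rates must be positive")
        if not np.isfinite(self.table["threshold_db"]).all():
            raise ValueError("reference thresholds must be finite")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())


def load_reference_csv(path, provenance: str = "") -> HumanReference:
    return HumanReference(pd.read_csv(path), provenance=provenance or str(path))


def _interp_log_rate(rates, thresholds, target_rates):
    """Linear interpolation in log2(rate); targets outside the span are
    clamped to the endpoint values (flagged by the caller)."""
    order = np.argsort(rates)
    return np.interp(np.log2(target_rates), np.log2(rates[order]),
                     thresholds[order])


def average_reference(ref: HumanReference, target_rates: dict) -> pd.DataFrame:
    """Subject-mean thresholds on each condition's target rate grid.

    ``target_rates`` maps condition name -> array of rates.  Returns a frame
    with columns condition, rate_hz, threshold_db, extrapolated (True where
    a target rate fell outside some subject's measured span and endpoint
    clamping was used).
    """
    rows = []
    for condition, rates in target_rates.items():
        sub = ref.table[ref.table["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no reference subjects for condition {condition!r}")
        rates = np.asarray(rates, dtype=float)
        per_subject = []
        clamped = np.zeros(rates.size, dtype=bool)
        for _, g in sub.groupby("subject"):
            r = g["rate_hz"].to_numpy(dtype=float)
            y = g["threshold_db"].to_numpy(dtype=float)
            per_subject.append(_interp_log_rate(r, y, rates))
            clamped |= (rates < r.min()) | (rates > r.max())
        mean = np.mean(per_subject, axis=0)
        for rate, thr, fl in zip(rates, mean, clamped):
            rows.append({"condition": condition, "rate_hz": rate,
                         "threshold_db": thr, "extrapolated": bool(fl)})
    return pd.DataFrame(rows)


def average_tmtfs(tmtfs) -> pd.DataFrame:
    """Average model TMTFs (same condition and rate grid) across models."""
    frames = [t.to_frame() for t in tmtfs]
    if not frames:
        raise ValueError("no TMTFs to average")
    table = pd.concat(frames)
    return (table.groupby(["condition", "rate_hz"], as_index=False)
            ["threshold_db"].mean())


def pool_conditions(model_table: pd.DataFrame, human_table: pd.DataFrame):
    """Align the two tables on (condition, rate) and return the pooled
    threshold vectors (model, human)."""
    merged = model_table.merge(human_table, on=["condition", "rate_hz"],
                               suffixes=("_model", "_human"))
    if len(merged) != len(model_table):
        raise ValueError("model and human tables do not align on "
                         "(condition, rate_hz)")
    return (merged["threshold_db_model"].to_numpy(),
            merged["threshold_db_human"].to_numpy())


def _check_pooled(y_model, y_human):
    y_model = np.asarray(y_model, dtype=float)
    y_human = np.asarray(y_human, dtype=float)
    if y_model.shape != y_human.shape or y_model.ndim != 1:
        raise ValueError("pooled vectors must be 1-D and equal length")
    return y_model, y_human


def pattern_similarity(y_model, y_human) -> float:
    """Pearson correlation of pooled model and human TMTFs; NaN when either
    vector has zero variance (undefined)."""
    y_model, y_human = _check_pooled(y_model, y_human)
    if np.std(y_model) == 0 or np.std(y_human) == 0:
        return float("nan")
    return float(pearsonr(y_model, y_human).statistic)


def discrepancy(y_model, y_human) -> float:
    """RMS deviation (dB) between pooled model and human TMTFs."""
    y_model, y_human = _check_pooled(y_model, y_human)
    return float(np.sqrt(np.mean((y_model - y_human) ** 2)))


def net_difference(y_model, y_human) -> float:
    """Mean signed deviation (dB); positive means higher model thresholds."""
    y_model, y_human = _check_pooled(y_model, y_human)
    return float(np.mean(y_model - y_human))


@dataclass
class SimilarityReport:
    """Per-layer pooled indices against one human reference."""

    table: pd.DataFrame  # layer, pattern_similarity, discrepancy_db, net_difference_db, n_points

    def to_json_dict(self) -> dict:
        return {
            str(int(r.layer)): {
                "pattern_similarity": r.pattern_similarity,
                "discrepancy_db": r.discrepancy_db,
                "net_difference_db": r.net_difference_db,
                "n_points": int(r.n_points),
            }
            for r in self.table.itertuples()
        }


def compare_tmtfs(tmtfs_by_layer: dict, human_mean: pd.DataFrame) -> SimilarityReport:
    """Pool each layer's TMTFs over conditions and compute the indices.

    ``tmtfs_by_layer`` maps layer index -> list of Tmtf (one per condition,
    already averaged over models if applicable); ``human_mean`` is the
    output of :func:`average_reference` on the same rate grids.
    """
    rows = []
    for layer, tmtfs in sorted(tmtfs_by_layer.items()):
        model_table = pd.concat([t.to_frame() for t in tmtfs])[
            ["condition", "rate_hz", "threshold_db"]]
        y_model, y_human = pool_conditions(model_table, human_mean)
        rows.append({
            "layer": layer,
            "pattern_similarity": pattern_similarity(y_model, y_human),
            "discrepancy_db": discrepancy(y_model, y_human),
            "net_difference_db": net_difference(y_model, y_human),
            "n_points": len(y_model),
        })
    return SimilarityReport(pd.DataFrame(rows))


def accuracy_similarity_correlation(accuracies, indices_by_layer: dict) -> pd.DataFrame:
    """Per-layer Pearson correlation between model recognition accuracy and a
    similarity index, Bonferroni-corrected over layers.

    ``accuracies``: one value per model (>= 3 models).  ``indices_by_layer``
    maps layer -> per-model index values.  Degenerate variance yields NaN.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 3:
        raise ValueError("need at least 3 models to correlate")
    n_layers = len(indices_by_layer)
    rows = []
    for layer, vals in sorted(indices_by_layer.items()):
        vals = np.asarray(vals, dtype=float)
        if vals.shape != acc.shape:
            raise ValueError(f"layer {layer}: need one index per model")
        if np.std(vals) == 0 or np.std(acc) == 0:
            r, p = float("nan"), float("nan")
        else:
            res = pearsonr(acc, vals)
            r, p = float(res.statistic), min(1.0, float(res.pvalue) * n_layers)
        rows.append({"layer": layer, "r": r, "p_corrected": p})
    return pd.DataFrame(rows)
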