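"""Simulated single-unit neurophysiology: AM tuning and brain-region mapping.

Each unit's response to fully modulated broadband noise probes yields two
tuning curves over AM rate: rate coding (time-averaged activity) and
synchrony coding (vector strength of the activity at the modulation rate,
computed after shifting the activity to be nonnegative, since ELU outputs
can be negative).  Each valid curve is characterized by its best rate (the
argmax, ties to the lowest rate) and its upper cutoff rate (the highest
rate at which the baseline-shifted curve stays within -3 dB of its peak,
log-rate interpolated).

Layer-to-brain-region similarity compares the layer's distribution of these
characteristic rates with a region's literature-derived distribution using
one minus the two-sample Kolmogorov-Smirnov distance, averaged over the
available characteristics.  A synthetic region fixture with the canonical
periphery-to-center trend (synchrony tuned to high rates peripherally, rate
tuning emerging centrally) ships for tests; literature samples can be
supplied in the same CSV format (region, characteristic, rate_hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import ks_2samp

from .am_stimuli import neurophys_probe_set

__all__ = [
    "TuningCurve",
    "RegionReference",
    "CHARACTERISTICS",
    "REGIONS",
    "measure_tuning",
    "vector_strength",
    "best_and_cutoff",
    "ks_similarity",
    "layer_region_map",
    "extract_characteristics",
    "load_region_reference",
    "synthetic_region_reference",
]

REGIONS = ("AN", "CN", "SOC", "NLL", "IC", "MGB", "AC")
CHARACTERISTICS = ("rate_best", "rate_cutoff", "sync_best", "sync_cutoff")

#: -3 dB criterion defining the upper cutoff on the baseline-shifted curve
CUTOFF_FRACTION = 1.0 / np.sqrt(2.0)

#: minimum peak-to-floor contrast for a curve to count as tuned
VALIDITY_RATIO = 1.2


@dataclass
class TuningCurve:
    """One unit's AM tuning: values per probe rate for one coding scheme,
    plus the derived best and upper-cutoff rates (NaN when invalid)."""

    unit_id: int
    coding: str  # "rate" | "sync"
    rates_hz: NDArray[np.float64]
    values: NDArray[np.float64]
    best_rate_hz: float = np.nan
    upper_cutoff_hz: float = np.nan
    valid: bool = False


def vector_strength(activity: np.ndarray, rate_hz: float, sample_rate: float) -> float:
    """Synchrony of a nonnegative-shifted activity trace to the modulator:
    VS(f) = |sum_t a(t) e^{-i 2 pi f t}| / sum_t a(t)."""
    a = np.asarray(activity, dtype=float)
    a = a - a.min()
    total = a.sum()
    if total <= 0:
        return 0.0
    t = np.arange(a.size) / sample_rate
    return float(np.abs(np.sum(a * np.exp(-2j * np.pi * rate_hz * t))) / total)


def measure_tuning(observer, rates_hz, sample_rate: float, duration_s: float = 0.5,
                   n_repeats: int = 10, rng_seed=0) -> list[TuningCurve]:
    """Measure rate- and synchrony-coded tuning curves for every unit of a
    frozen layer.

    Probes are fully modulated broadband noise with independent carriers per
    repeat.  Rates at or above the activity Nyquist (activities are sampled
    at the input rate) are rejected.  Bit-for-bit reproducible for a fixed
    seed.
    """
    rates = np.asarray(sorted(float(r) for r in rates_hz))
    probes = neurophys_probe_set(rates, sample_rate, duration_s, n_repeats, rng_seed)
    n_units = None
    rate_t, sync_t = [], []
    for rate in rates:
        acts = [observer.activations(w) for w in probes[rate]]
        n_units = acts[0].shape[0]
        rate_t.append(np.mean([a.mean(axis=1) for a in acts], axis=0))
        sync_t.append(np.mean([
            [vector_strength(a[u], rate, sample_rate) for u in range(n_units)]
            for a in acts
        ], axis=0))
    rate_t = np.asarray(rate_t).T   # unit x rate
    sync_t = np.asarray(sync_t).T
    curves = []
    for u in range(n_units):
        for coding, vals in (("rate", rate_t[u]), ("sync", sync_t[u])):
            best, cutoff, valid = best_and_cutoff(vals, rates)
            curves.append(TuningCurve(u, coding, rates, vals.copy(),
                                      best, cutoff, valid))
    return curves


def best_and_cutoff(values, rates_hz, validity_ratio: float = VALIDITY_RATIO):
    """Best rate and upper cutoff of one tuning curve.

    Best rate: argmax (ties resolve to the lowest rate).  Upper cutoff: the
    highest rate at which the baseline-shifted curve still reaches
    ``CUTOFF_FRACTION`` of its peak, interpolated linearly in log2(rate)
    between samples; the top probe rate when the curve never drops.  Curves
    whose peak-to-floor contrast is below ``validity_ratio`` are invalid
    (returns NaNs and ``False``).
    """
    v = np.asarray(values, dtype=float)
    rates = np.asarray(rates_hz, dtype=float)
    if v.size != rates.size or v.size < 3:
        raise ValueError("need >= 3 rates with one value each")
    if not np.all(np.isfinite(v)):
        raise ValueError("tuning values must be finite")
    vmax, vmin = v.max(), v.min()
    # contrast criterion: (peak - floor) relative to the peak magnitude
    if vmax - vmin <= (validity_ratio - 1.0) * max(abs(vmax), 1e-12):
        return np.nan, np.nan, False
    s = v - vmin
    best_idx = int(np.argmax(s))
    best = float(rates[best_idx])
    thresh = CUTOFF_FRACTION * s[best_idx]
    cutoff = float(rates[-1])
    for j in range(best_idx + 1, s.size):
        if s[j] < thresh:
            x0, x1 = np.log2(rates[j - 1]), np.log2(rates[j])
            frac = (s[j - 1] - thresh) / (s[j - 1] - s[j])
            cutoff = float(2.0 ** (x0 + frac * (x1 - x0)))
            break
    return best, cutoff, True


def ks_similarity(sample_a, sample_b) -> float:
    """1 - Kolmogorov-Smirnov distance of two rate samples (ECDFs over log
    rate; the KS statistic is invariant to the monotone log transform)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("rates must be positive")
    return float(1.0 - ks_2samp(np.log(a), np.log(b)).statistic)


def extract_characteristics(curves: list[TuningCurve]) -> dict[str, np.ndarray]:
    """Distributions of best and upper-cutoff rates over the layer's valid
    units, keyed rate_best / rate_cutoff / sync_best / sync_cutoff."""
    out = {}
    for coding in ("rate", "sync"):
        sel = [c for c in curves if c.coding == coding and c.valid]
        out[f"{coding}_best"] = np.array([c.best_rate_hz for c in sel])
        out[f"{coding}_cutoff"] = np.array([c.upper_cutoff_hz for c in sel])
    return out


@dataclass
class RegionReference:
    """Literature-style samples of characteristic AM rates per brain region.

    ``table`` columns: region, characteristic, rate_hz (one row per sampled
    neuron-level value).
    """

    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        required = {"region", "characteristic", "rate_hz"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"region table missing columns {sorted(missing)}")
        if (self.table["rate_hz"] <= 0).any():
            raise ValueError("all reference rates must be positive")

    @property
    def regions(self) -> list[str]:
        return [r for r in REGIONS if r in set(self.table["region"])] + sorted(
            set(self.table["region"]) - set(REGIONS))

    def sample(self, region: str, characteristic: str) -> np.ndarray:
        sel = self.table[(self.table["region"] == region)
                         & (self.table["characteristic"] == characteristic)]
        return sel["rate_hz"].to_numpy(dtype=float)


def load_region_reference(path, provenance: str = "") -> RegionReference:
    return RegionReference(pd.read_csv(path), provenance=provenance or str(path))


def synthetic_region_reference() -> RegionReference:
    """The bundled synthetic region fixture (see data/synthetic_region_tuning.csv)."""
    with resources.files("modsense.data").joinpath(
            "synthetic_region_tuning.csv").open() as fh:
        return RegionReference(pd.read_csv(fh), provenance="synthetic fixture")


def layer_region_map(characteristics_by_layer: dict, ref: RegionReference) -> pd.DataFrame:
    """Layer x region similarity matrix.

    For every characteristic present with a nonempty sample on both sides,
    compute ``ks_similarity``; the combined score is the mean over those
    characteristics.  Layers with no valid characteristic are omitted.
    Returns a tidy frame: layer, region, characteristic ("combined" rows
    included), similarity.
    """
    rows = []
    for layer, chars in sorted(characteristics_by_layer.items()):
        usable = {k: v for k, v in chars.items() if np.size(v) > 0}
        if not usable:
            continue
        for region in ref.regions:
            sims = {}
            for char, sample in usable.items():
                ref_sample = ref.sample(region, char)
                if ref_sample.size == 0:
                    continue
                sims[char] = ks_similarity(sample, ref_sample)
            if not sims:
                continue
            for char, s in sims.items():
                rows.append({"layer": layer, "region": region,
                             "characteristic": char, "similarity": s})
            rows.append({"layer": layer, "region": region,
                         "characteristic": "combined",
                         "similarity": float(np.mean(list(sims.values())))})
    return pd.DataFrame(rows)
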