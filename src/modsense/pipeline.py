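"""End-to-end experiment orchestration.

Runs the full chain — synthetic corpus, recognizer training, layerwise TMTF
measurement, comparison with a human reference, simulated neurophysiology
and brain-region mapping — from a single seeded configuration, writing every
stage's artifacts (CSV tables, JSON reports, the checkpoint and the config
copy) into a run directory.  Re-running the same configuration reproduces
all outputs; the global seed fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model as model_mod
from . import neurophys as neuro_mod
from .am_stimuli import AmConditionSpec, standard_conditions
from .model import Architecture, DilatedConvNet, TrainingConfig, evaluate_recognition, train
from .neurophys import extract_characteristics, layer_region_map, measure_tuning
from .psychophysics import LayerObserver, measure_tmtf
from .synthetic_data import CategoryParams, SyntheticCorpusSpec, generate_corpus
from .tmtf_compare import average_reference, compare_tmtfs, load_reference_csv

logger = logging.getLogger("modsense")

__all__ = ["RunConfig", "run_experiment", "toy_run_config", "toy_corpus_spec",
           "toy_architecture", "toy_training_config", "toy_conditions"]


# ---------------------------------------------------------------------------
# Desk-scale presets (the demo experiment the package runs end to end)
# ---------------------------------------------------------------------------

def toy_corpus_spec(rng_seed: int = 0) -> SyntheticCorpusSpec:
    """Three AM-separable categories at 8 kHz (0.5 s clips, 60 per category):
    modulation centers 8/32/128 Hz crossed with carrier tilts -10/0/+10
    dB/octave."""
    return SyntheticCorpusSpec(
        n_categories=3, clips_per_category=60, sample_rate=8000.0,
        clip_duration_s=0.5, noise_floor=0.02,
        categories=(
            CategoryParams(8.0, 0.3, 1.0, -10.0),
            CategoryParams(32.0, 0.3, 1.0, 0.0),
            CategoryParams(128.0, 0.3, 1.0, 10.0),
        ),
        rng_seed=rng_seed,
    )


def toy_architecture(n_categories: int = 3) -> Architecture:
    """3 layers x 32 units, 1500-sample input window (0.1875 s at 8 kHz)."""
    return Architecture(
        n_layers=3, units_per_layer=32, filter_sizes=(5, 5, 5),
        dilations=(60, 80, 100), n_categories=n_categories,
        input_window_samples=1500,
    )


def toy_training_config(rng_seed: int = 0) -> TrainingConfig:
    return TrainingConfig(learning_rate=3e-3, patience_epochs=30,
                          max_epochs=120, windows_per_clip=6, batch_size=32,
                          rng_seed=rng_seed)


def toy_conditions(sample_rate: float = 8000.0) -> dict[str, AmConditionSpec]:
    """A reduced condition set for the demo run: the long-broadband condition
    with fewer rates and trials, scaled to the toy sample rate."""
    base = standard_conditions(sample_rate=sample_rate, center_freq_hz=2000.0,
                               target_rms=1.0)
    c = base["broadband_long"]
    return {"broadband_long": dataclasses.replace(
        c, duration_s=0.5, n_rates=2, rate_range_hz=(8.0, 64.0))}


@dataclass
class RunConfig:
    """Everything one experiment needs; serialized alongside its outputs."""

    out_dir: str
    seed: int = 0
    corpus_spec: SyntheticCorpusSpec | None = None
    architecture: Architecture | None = None
    training: TrainingConfig | None = None
    conditions: dict | None = None          # name -> AmConditionSpec
    layers: tuple[int, ...] = ()            # empty: all layers
    detector: str = "logistic"
    n_trials: int = 16
    probe_rates: tuple[float, ...] = (4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0)
    probe_repeats: int = 4
    human_reference_csv: str | None = None  # None: bundled synthetic fixture
    region_reference_csv: str | None = None
    compare_enabled: bool = True

    def resolved(self) -> "RunConfig":
        cfg = dataclasses.replace(self)
        if cfg.corpus_spec is None:
            cfg.corpus_spec = toy_corpus_spec(rng_seed=self.seed)
        if cfg.architecture is None:
            cfg.architecture = toy_architecture(cfg.corpus_spec.n_categories)
        if cfg.training is None:
            cfg.training = toy_training_config(rng_seed=self.seed)
        if cfg.conditions is None:
            cfg.conditions = toy_conditions(cfg.corpus_spec.sample_rate)
        if not cfg.layers:
            cfg.layers = tuple(range(1, cfg.architecture.n_layers + 1))
        return cfg

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["corpus_spec"] = dataclasses.asdict(self.corpus_spec) if self.corpus_spec else None
        d["architecture"] = dataclasses.asdict(self.architecture) if self.architecture else None
        d["training"] = dataclasses.asdict(self.training) if self.training else None
        d["conditions"] = ({k: dataclasses.asdict(v) for k, v in self.conditions.items()}
                           if self.conditions else None)
        return yaml.safe_dump(d, sort_keys=False)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds fanned out from the global seed."""
    ss = np.random.SeedSequence(seed)
    names = ("corpus", "train", "tmtf", "neurophys")
    return {n: int(c.generate_state(1)[0] % (2**31))
            for n, c in zip(names, ss.spawn(len(names)))}


def _bundled_reference(name: str):
    return resources.files("modsense.data").joinpath(name)


def run_experiment(config: RunConfig) -> Path:
    """Run corpus -> train -> TMTF -> compare -> neurophysiology.

    Each stage consumes only earlier stages' outputs and writes its artifacts
    before the next begins; failures abort with a stage-tagged error.
    Returns the run directory.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)

    # fail fast on configuration errors before any compute
    if cfg.compare_enabled:
        href = (Path(cfg.human_reference_csv) if cfg.human_reference_csv
                else _bundled_reference("synthetic_human_tmtf.csv"))
        if not href.is_file():
            raise FileNotFoundError(
                f"[configure] human reference CSV not found: {href}")
    rref = (Path(cfg.region_reference_csv) if cfg.region_reference_csv
            else _bundled_reference("synthetic_region_tuning.csv"))
    if not rref.is_file():
        raise FileNotFoundError(f"[configure] region reference CSV not found: {rref}")
    (out / "config.yaml").write_text(cfg.to_yaml())
    (out / "stage_seeds.json").write_text(json.dumps(seeds))

    def _stage(name):
        logger.info("stage %s starting", name)

    try:
        _stage("corpus")
        spec = dataclasses.replace(cfg.corpus_spec, rng_seed=seeds["corpus"])
        corpus = generate_corpus(spec)
        corpus.manifest.to_csv(out / "corpus_manifest.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"[corpus] {e}") from e

    try:
        _stage("train")
        up_c, up_l = corpus.split("update")
        es_c, es_l = corpus.split("early_stop")
        va_c, va_l = corpus.split("validation")
        net = DilatedConvNet(cfg.architecture, rng_seed=seeds["train"])
        tcfg = dataclasses.replace(cfg.training, rng_seed=seeds["train"])
        trained = train(net, up_c, up_l, es_c, es_l, tcfg)
        val_acc = evaluate_recognition(trained, va_c, va_l)
        trained.net.save(out / "checkpoint.npz")
        trained.training_log.to_csv(out / "training_log.csv", index=False)
        (out / "recognition.json").write_text(json.dumps({
            "validation_accuracy": val_acc,
            "chance_level": model_mod.chance_level(cfg.corpus_spec.n_categories),
            "early_stop_accuracy": trained.best_accuracy,
        }))
    except Exception as e:
        raise RuntimeError(f"[train] {e}") from e

    try:
        _stage("tmtf")
        tmtf_frames, raw_frames = [], []
        tmtfs_by_layer = {}
        for layer in cfg.layers:
            obs = LayerObserver(trained, layer)
            per_layer = []
            for cname, cond in cfg.conditions.items():
                tmtf, raw = measure_tmtf(obs, cond, detector=cfg.detector,
                                         n_trials=cfg.n_trials,
                                         rng_seed=seeds["tmtf"] + layer,
                                         return_raw=True)
                per_layer.append(tmtf)
                frame = tmtf.to_frame()
                frame["seed"] = seeds["tmtf"] + layer
                tmtf_frames.append(frame)
                raw["layer"], raw["condition"] = layer, cname
                raw_frames.append(raw)
            tmtfs_by_layer[layer] = per_layer
        pd.concat(tmtf_frames).to_csv(out / "tmtf.csv", index=False)
        pd.concat(raw_frames).to_csv(out / "psychometric_raw.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"[tmtf] {e}") from e

    if cfg.compare_enabled:
        try:
            _stage("compare")
            ref = load_reference_csv(href)
            grids = {c.name: c.rates_hz for c in cfg.conditions.values()}
            human_mean = average_reference(ref, grids)
            report = compare_tmtfs(tmtfs_by_layer, human_mean)
            (out / "similarity.json").write_text(
                json.dumps(report.to_json_dict(), indent=1))
        except Exception as e:
            raise RuntimeError(f"[compare] {e}") from e

    try:
        _stage("neurophys")
        sr = cfg.corpus_spec.sample_rate
        rates = [r for r in cfg.probe_rates if r < sr / 2]
        tuning_rows, chars_by_layer = [], {}
        for layer in cfg.layers:
            obs = LayerObserver(trained, layer)
            curves = measure_tuning(obs, rates, sr, duration_s=0.5,
                                    n_repeats=cfg.probe_repeats,
                                    rng_seed=seeds["neurophys"] + layer)
            chars_by_layer[layer] = extract_characteristics(curves)
            for c in curves:
                for r, v in zip(c.rates_hz, c.values):
                    tuning_rows.append({
                        "layer": layer, "unit": c.unit_id, "coding": c.coding,
                        "rate_hz": r, "value": v, "best_rate_hz": c.best_rate_hz,
                        "upper_cutoff_hz": c.upper_cutoff_hz, "valid": c.valid,
                    })
        pd.DataFrame(tuning_rows).to_csv(out / "tuning.csv", index=False)
        region_ref = neuro_mod.load_region_reference(rref)
        sim = layer_region_map(chars_by_layer, region_ref)
        sim.to_csv(out / "region_similarity.csv", index=False)
        combined = sim[sim["characteristic"] == "combined"]
        (out / "region_similarity.json").write_text(json.dumps({
            str(layer): {row.region: row.similarity
                         for row in g.itertuples()}
            for layer, g in combined.groupby("layer")
        }, indent=1))
    except Exception as e:
        raise RuntimeError(f"[neurophys] {e}") from e

    return out
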