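"""Synthetic labeled sound corpora with category-specific AM statistics.

Stands in for real everyday-sound / speech corpora so that training,
degradation, psychophysics and neurophysiology are all testable without
downloads.  Each category is defined by a modulation-spectrum bump (a
Gaussian on the log AM-rate axis: center rate, log-bandwidth, depth) and a
carrier spectral tilt (dB/octave); each clip draws a fresh noise carrier and
a fresh modulator from the category's bump, so within-category variability
makes classification non-trivial while the category statistics remain
discriminable — the "natural AM statistics" situation the recognizer is
optimized for.

The degraded-corpus operation maps a corpus through the Env/TFS chimera
constructions (single- or multi-band), transforming only the audio: labels,
splits and manifest schema are unchanged, and psychophysical stimuli are
never degraded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.io import wavfile

from .signal_ops import (
    build_erb_filterbank,
    highpass20,
    multiband_env_signal,
    multiband_tfs_signal,
    ramp_and_scale,
    single_band_env_signal,
    single_band_tfs_signal,
)

__all__ = [
    "CategoryParams",
    "SyntheticCorpusSpec",
    "Corpus",
    "generate_corpus",
    "degraded_corpus",
    "write_corpus",
    "read_corpus",
    "DEGRADATION_MODES",
]

DEGRADATION_MODES = ("env1", "envN", "tfs1", "tfsN")


@dataclass(frozen=True)
class CategoryParams:
    """Generative parameters of one sound category."""

    mod_center_hz: float      # center of the modulation-spectrum bump
    mod_log_bw: float         # bump width in octaves (sigma on log2 rate)
    mod_depth: float          # envelope modulation depth, 0..~1
    carrier_tilt_db_oct: float  # spectral tilt of the noise carrier


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Specification of a synthetic corpus.

    Default: 10 categories x 40 one-second clips at 16 kHz with modulation
    centers log-spaced 4-128 Hz and carrier tilts spanning -6..+6 dB/octave,
    split 0.6/0.2/0.2 into parameter-update, early-stopping and validation
    sets.  Clips are generated at unit RMS.
    """

    n_categories: int = 10
    clips_per_category: int = 40
    sample_rate: float = 16000.0
    clip_duration_s: float = 1.0
    categories: tuple[CategoryParams, ...] = ()
    noise_floor: float = 0.05
    target_rms: float = 1.0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    rng_seed: int = 0

    def __post_init__(self):
        if not self.categories:
            object.__setattr__(self, "categories",
                               default_categories(self.n_categories))
        if len(self.categories) != self.n_categories:
            raise ValueError("need one CategoryParams per category")
        if len({(c.mod_center_hz, c.carrier_tilt_db_oct) for c in self.categories}) \
                != self.n_categories:
            raise ValueError("category parameter sets must be pairwise distinct")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        slowest = min(c.mod_center_hz for c in self.categories)
        if self.clip_duration_s * slowest < 2.0:
            raise ValueError(
                f"clip duration {self.clip_duration_s}s too short for the "
                f"slowest modulation center ({slowest} Hz): need >= 2 cycles"
            )


def default_categories(n: int) -> tuple[CategoryParams, ...]:
    """Log-spaced modulation centers (4-128 Hz) crossed with carrier tilts."""
    if n < 1:
        raise ValueError("need at least one category")
    centers = np.geomspace(4.0, 128.0, n) if n > 1 else np.array([16.0])
    tilts = np.linspace(-6.0, 6.0, n) if n > 1 else np.array([0.0])
    return tuple(
        CategoryParams(mod_center_hz=float(c), mod_log_bw=0.5,
                       mod_depth=0.9, carrier_tilt_db_oct=float(t))
        for c, t in zip(centers, tilts)
    )


@dataclass
class Corpus:
    """Labeled clips plus a manifest (clip_id, category, split, seed)."""

    clips: list[NDArray[np.float64]]
    manifest: pd.DataFrame
    sample_rate: float
    degradation_mode: str | None = None

    def split(self, name: str) -> tuple[list, np.ndarray]:
        """(clips, integer labels) of one split: update|early_stop|validation."""
        mask = self.manifest["split"] == name
        if not mask.any():
            raise ValueError(f"empty split {name!r}")
        idx = np.flatnonzero(mask.to_numpy())
        labels = self.manifest.loc[mask, "category"].to_numpy()
        return [self.clips[i] for i in idx], labels

    @property
    def n_categories(self) -> int:
        return int(self.manifest["category"].nunique())


def _tilted_noise(n, sample_rate, tilt_db_oct, rng):
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    gain = np.zeros_like(f)
    # tilt_db_oct dB per octave relative to 1 kHz
    gain[1:] = (f[1:] / 1000.0) ** (tilt_db_oct / (20.0 * np.log10(2.0)))
    return np.fft.irfft(spec * gain, n=n)


def _bump_modulator(n, sample_rate, center_hz, log_bw, rng):
    """Noise modulator band-limited by a Gaussian bump on the log2-rate axis."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    w = np.zeros_like(f)
    pos = f > 0
    w[pos] = np.exp(-0.5 * (np.log2(f[pos] / center_hz) / log_bw) ** 2)
    m = np.fft.irfft(spec * w, n=n)
    sd = np.std(m)
    return m / sd if sd > 0 else m


def _synthesize_clip(cat: CategoryParams, n: int, sample_rate: float,
                     noise_floor: float, target_rms: float,
                     rng: np.random.Generator) -> np.ndarray:
    carrier = _tilted_noise(n, sample_rate, cat.carrier_tilt_db_oct, rng)
    carrier /= np.sqrt(np.mean(carrier ** 2))
    mod = _bump_modulator(n, sample_rate, cat.mod_center_hz, cat.mod_log_bw, rng)
    envelope = np.maximum(1.0 + cat.mod_depth * mod, 0.0)
    y = carrier * envelope + noise_floor * rng.standard_normal(n)
    y = highpass20(y, sample_rate)
    return ramp_and_scale(y, sample_rate, target_rms)


def generate_corpus(spec: SyntheticCorpusSpec) -> Corpus:
    """Generate a labeled corpus; byte-identical for a fixed seed.

    Per-clip generators are spawned deterministically from the corpus seed,
    so any clip can be regenerated independently.
    """
    n = int(round(spec.clip_duration_s * spec.sample_rate))
    total = spec.n_categories * spec.clips_per_category
    children = np.random.SeedSequence(spec.rng_seed).spawn(total + 1)
    split_rng = np.random.default_rng(children[-1])

    clips, rows = [], []
    i = 0
    for cat_idx, cat in enumerate(spec.categories):
        for j in range(spec.clips_per_category):
            rng = np.random.default_rng(children[i])
            clips.append(_synthesize_clip(cat, n, spec.sample_rate,
                                          spec.noise_floor, spec.target_rms, rng))
            rows.append({"clip_id": f"cat{cat_idx:02d}_clip{j:03d}",
                         "category": cat_idx, "seed_index": i})
            i += 1

    f_up, f_es, _ = spec.split_fractions
    splits = np.empty(total, dtype=object)
    for cat_idx in range(spec.n_categories):
        idx = np.flatnonzero(np.array([r["category"] for r in rows]) == cat_idx)
        idx = split_rng.permutation(idx)
        n_up = int(round(f_up * len(idx)))
        n_es = int(round(f_es * len(idx)))
        splits[idx[:n_up]] = "update"
        splits[idx[n_up:n_up + n_es]] = "early_stop"
        splits[idx[n_up + n_es:]] = "validation"
    manifest = pd.DataFrame(rows)
    manifest["split"] = splits
    return Corpus(clips=clips, manifest=manifest, sample_rate=spec.sample_rate)


def degraded_corpus(corpus: Corpus, mode: str, rng_seed: int = 0) -> Corpus:
    """Map every clip through an Env/TFS chimera construction.

    Modes: ``env1``/``tfs1`` operate on the full-band signal, ``envN``/
    ``tfsN`` per band of the ERB filterbank built for the corpus Nyquist.
    The manifest is carried over unchanged.
    """
    if mode not in DEGRADATION_MODES:
        raise ValueError(f"mode must be one of {DEGRADATION_MODES}, got {mode!r}")
    sr = corpus.sample_rate
    bank = build_erb_filterbank(20.0, sr / 2.0) if mode in ("envN", "tfsN") else None
    children = np.random.SeedSequence(rng_seed).spawn(len(corpus.clips))
    out = []
    for i, clip in enumerate(corpus.clips):
        if mode == "env1":
            out.append(single_band_env_signal(clip, sr, np.random.default_rng(children[i])))
        elif mode == "tfs1":
            out.append(single_band_tfs_signal(clip, sr))
        elif mode == "envN":
            out.append(multiband_env_signal(clip, bank, sr, np.random.default_rng(children[i])))
        else:
            out.append(multiband_tfs_signal(clip, bank, sr))
    return Corpus(clips=out, manifest=corpus.manifest.copy(),
                  sample_rate=sr, degradation_mode=mode)


# ---------------------------------------------------------------------------
# WAV + manifest I/O (same schema as the real-dataset adapters)
# ---------------------------------------------------------------------------

def write_corpus(corpus: Corpus, out_dir) -> Path:
    """Write clips as float32 WAV plus a manifest.csv; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = corpus.manifest.copy()
    manifest["filename"] = [f"{cid}.wav" for cid in manifest["clip_id"]]
    if corpus.degradation_mode:
        manifest["mode"] = corpus.degradation_mode
    for fname, clip in zip(manifest["filename"], corpus.clips):
        wavfile.write(out / fname, int(corpus.sample_rate),
                      np.asarray(clip, dtype=np.float32))
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def read_corpus(in_dir) -> Corpus:
    """Read a corpus written by :func:`write_corpus` (or any directory with
    the same manifest.csv schema and PCM/float WAV files)."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    clips = []
    for fname in manifest["filename"]:
        sr, data = wavfile.read(in_dir / fname)
        if np.issubdtype(data.dtype, np.integer):
            data = data / np.iinfo(data.dtype).max
        clips.append(np.asarray(data, dtype=float))
    mode = manifest["mode"].iloc[0] if "mode" in manifest.columns else None
    return Corpus(clips=clips, manifest=manifest, sample_rate=float(sr),
                  degradation_mode=mode)
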