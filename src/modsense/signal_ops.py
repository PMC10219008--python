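"""Envelope / temporal-fine-structure signal operations.

This module provides the low-level waveform machinery used throughout the
package: Hilbert analytic-signal decomposition into amplitude envelope (Env)
and temporal fine structure (TFS), an ERB-spaced brick-wall filterbank, FFT
bandpass filtering, onset/offset ramps with exact RMS scaling, and the four
Env/TFS "chimera" constructions used to degrade training corpora while
leaving either the envelope or the fine structure intact.

Conventions
-----------
* Waveforms are 1-D float arrays sampled at ``sample_rate`` Hz.
* Env and TFS are the magnitude and phase of the Hilbert analytic signal;
  ``real(Env * exp(i * TFS))`` reconstructs the waveform.
* The filterbank partitions [0, Nyquist] with brick-wall FFT bands whose
  edges sit at ERB-scale midpoints between one-ERB-spaced centers, so the
  sub-band signals sum exactly to the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.signal import hilbert

__all__ = [
    "AnalyticDecomposition",
    "ErbFilterbank",
    "erb_bandwidth",
    "erb_number",
    "erb_number_inverse",
    "hilbert_decompose",
    "build_erb_filterbank",
    "bandpass_fft",
    "single_band_env_signal",
    "single_band_tfs_signal",
    "multiband_env_signal",
    "multiband_tfs_signal",
    "ramp_and_scale",
    "apply_ramps",
    "highpass20",
    "rms",
]

Waveform = NDArray[np.float64]


# ---------------------------------------------------------------------------
# Basic helpers
# ---------------------------------------------------------------------------

def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of a signal."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty signal is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def _check_waveform(x, min_len: int = 2) -> Waveform:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D waveform, got shape {x.shape}")
    if x.size < min_len:
        raise ValueError(f"waveform too short: {x.size} < {min_len} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite values")
    return x


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Hilbert Env/TFS decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticDecomposition:
    """Envelope and fine-structure phase of the Hilbert analytic signal.

    ``env`` is the nonnegative instantaneous amplitude, ``tfs_phase`` the
    instantaneous phase in radians.  ``recompose`` reproduces the original
    waveform to numerical tolerance.
    """

    env: Waveform
    tfs_phase: Waveform
    sample_rate: float

    def __post_init__(self):
        if self.env.shape != self.tfs_phase.shape:
            raise ValueError("env and tfs_phase must have the same length")
        if np.any(self.env < 0):
            raise ValueError("envelope must be nonnegative")

    def recompose(self) -> Waveform:
        """real(env * exp(i * tfs_phase)) — the original waveform."""
        return self.env * np.cos(self.tfs_phase)


def hilbert_decompose(waveform, sample_rate: float) -> AnalyticDecomposition:
    """Split a waveform into its Hilbert envelope and TFS phase.

    The envelope is the magnitude and the TFS the phase of the complex
    analytic signal.  Edge effects of the full-clip Hilbert transform are
    accepted (no framing); envelope-based measurements should discard a few
    ramp lengths at each end.
    """
    x = _check_waveform(waveform)
    analytic = hilbert(x)
    return AnalyticDecomposition(
        env=np.abs(analytic),
        tfs_phase=np.unwrap(np.angle(analytic)),
        sample_rate=float(sample_rate),
    )


# ---------------------------------------------------------------------------
# ERB scale and filterbank
# ---------------------------------------------------------------------------

def erb_bandwidth(f_hz) -> np.ndarray | float:
    """Equivalent rectangular bandwidth at frequency ``f_hz`` (Glasberg-Moore):
    ERB(f) = 24.7 * (4.37 * f / 1000 + 1)."""
    return 24.7 * (4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_number(f_hz) -> np.ndarray | float:
    """ERB-number (Cam) scale: E(f) = 21.4 * log10(4.37 * f / 1000 + 1)."""
    return 21.4 * np.log10(4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_number_inverse(erb) -> np.ndarray | float:
    """Frequency in Hz at a given ERB number."""
    return (np.power(10.0, np.asarray(erb, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


@dataclass(frozen=True)
class ErbFilterbank:
    """Brick-wall filterbank with one-ERB-spaced center frequencies.

    Centers start at ``f_low`` and step exactly one ERB on the ERB-number
    scale up to the Nyquist frequency.  Band edges sit at the ERB-scale
    midpoints between adjacent centers (0 below the first, Nyquist above the
    last), so the bands partition [0, Nyquist] and the sub-band signals sum
    exactly to the input.
    """

    center_freqs: NDArray[np.float64]
    band_edges: NDArray[np.float64]
    f_low: float
    nyquist: float

    @property
    def n_bands(self) -> int:
        return len(self.center_freqs)

    def band(self, i: int) -> tuple[float, float]:
        """(low, high) edge frequencies of band ``i``."""
        return float(self.band_edges[i]), float(self.band_edges[i + 1])

    def decompose(self, waveform, sample_rate: float) -> list[Waveform]:
        """Split a waveform into its sub-band signals.

        Each rFFT bin is assigned to exactly one band (half-open intervals,
        the top band taking the Nyquist bin), so the returned signals sum to
        the input to machine precision.
        """
        x = _check_waveform(self._check_rate(waveform, sample_rate))
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
        bands = []
        for i in range(self.n_bands):
            lo, hi = self.band(i)
            mask = (freqs >= lo) & (freqs < hi)
            if i == self.n_bands - 1:
                mask |= freqs >= hi
            bands.append(np.fft.irfft(spec * mask, n=x.size))
        return bands

    def _check_rate(self, waveform, sample_rate: float):
        if abs(sample_rate / 2.0 - self.nyquist) > 1e-6 * self.nyquist:
            raise ValueError(
                f"filterbank built for Nyquist {self.nyquist} Hz but waveform "
                f"sampled at {sample_rate} Hz"
            )
        return waveform


def build_erb_filterbank(f_low: float = 20.0, nyquist: float = 22050.0) -> ErbFilterbank:
    """Build the ERB-spaced brick-wall filterbank.

    Centers are spaced every one ERB on the ERB-number scale starting at
    ``f_low``; all centers at or below ``nyquist`` are kept.  At a 22.05 kHz
    Nyquist this yields 42 bands, at 8 kHz it yields 33.
    """
    if not 0 < f_low < nyquist:
        raise ValueError(f"need 0 < f_low < nyquist, got ({f_low}, {nyquist})")
    e_low = float(erb_number(f_low))
    e_high = float(erb_number(nyquist))
    n_centers = int(np.floor(e_high - e_low)) + 1
    centers = np.asarray(erb_number_inverse(e_low + np.arange(n_centers)))
    # numerical guard: centers must not exceed the Nyquist
    centers = centers[centers <= nyquist * (1 + 1e-12)]
    mid_erb = e_low + np.arange(len(centers) - 1) + 0.5
    edges = np.concatenate(([0.0], np.atleast_1d(erb_number_inverse(mid_erb)), [nyquist]))
    return ErbFilterbank(
        center_freqs=centers, band_edges=edges, f_low=float(f_low), nyquist=float(nyquist)
    )


# ---------------------------------------------------------------------------
# FFT bandpass / highpass
# ---------------------------------------------------------------------------

def bandpass_fft(waveform, lo: float, hi: float, sample_rate: float) -> Waveform:
    """Brick-wall bandpass via the discrete Fourier transform.

    Spectral components with lo <= f <= hi are kept, everything else is
    zeroed; the output is real-valued and the same length as the input.
    """
    x = _check_waveform(waveform)
    nyq = sample_rate / 2.0
    if not (0 <= lo < hi <= nyq * (1 + 1e-12)):
        raise ValueError(f"invalid band [{lo}, {hi}] for Nyquist {nyq}")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    mask = (freqs >= lo) & (freqs <= hi)
    return np.fft.irfft(spec * mask, n=x.size)


def highpass20(waveform, sample_rate: float) -> Waveform:
    """High-pass at 20 Hz (removes DC and infrasonic drift)."""
    return bandpass_fft(waveform, 20.0, sample_rate / 2.0, sample_rate)


# ---------------------------------------------------------------------------
# Env / TFS chimera constructions
# ---------------------------------------------------------------------------

def single_band_env_signal(x, sample_rate: float, rng_seed) -> Waveform:
    """Keep the full-band envelope, replace the fine structure with noise.

    Output = real(Env_x(t) * exp(i * TFS_wn(t))) where ``wn`` is white noise
    with the same RMS as ``x``.
    """
    x = _check_waveform(x)
    rng = _as_rng(rng_seed)
    noise = rng.standard_normal(x.size)
    target = rms(x)
    if target > 0:
        noise *= target / rms(noise)
    env = hilbert_decompose(x, sample_rate).env
    tfs_wn = hilbert_decompose(noise, sample_rate).tfs_phase if target > 0 else np.zeros_like(x)
    return env * np.cos(tfs_wn)


def single_band_tfs_signal(x, sample_rate: float) -> Waveform:
    """Keep the full-band fine structure, flatten the envelope.

    Output = real(FlatEnv_x * exp(i * TFS_x(t))) with
    FlatEnv_x = RMS(Env_x(t)); the analytic magnitude before the real-part
    projection is exactly constant.  An all-zero input maps to zeros.
    """
    x = _check_waveform(x)
    if not np.any(x):
        return np.zeros_like(x)
    dec = hilbert_decompose(x, sample_rate)
    return rms(dec.env) * np.cos(dec.tfs_phase)


def multiband_env_signal(x, bank: ErbFilterbank, sample_rate: float, rng_seed) -> Waveform:
    """Per-band envelope preserved, per-band fine structure replaced by a
    band-matched noise carrier; bands are summed to form the output."""
    x = _check_waveform(x)
    rng = _as_rng(rng_seed)
    noise = rng.standard_normal(x.size)
    target = rms(x)
    if target > 0:
        noise *= target / rms(noise)
    x_bands = bank.decompose(x, sample_rate)
    n_bands = bank.decompose(noise, sample_rate)
    out = np.zeros_like(x)
    for xb, nb in zip(x_bands, n_bands):
        if not np.any(xb):
            continue
        env = hilbert_decompose(xb, sample_rate).env
        if np.any(nb):
            phase = hilbert_decompose(nb, sample_rate).tfs_phase
            out += env * np.cos(phase)
        else:  # degenerate: silent donor band, keep the band's own carrier
            out += xb
    return out


def multiband_tfs_signal(x, bank: ErbFilterbank, sample_rate: float) -> Waveform:
    """Per-band fine structure preserved, per-band envelope flattened to its
    RMS; bands are summed to form the output."""
    x = _check_waveform(x)
    out = np.zeros_like(x)
    for xb in bank.decompose(x, sample_rate):
        if not np.any(xb):
            continue
        dec = hilbert_decompose(xb, sample_rate)
        out += rms(dec.env) * np.cos(dec.tfs_phase)
    return out


# ---------------------------------------------------------------------------
# Ramps and RMS scaling
# ---------------------------------------------------------------------------

def apply_ramps(x, sample_rate: float, ramp_ms: float = 10.0) -> Waveform:
    """Apply raised-cosine onset and offset ramps of ``ramp_ms`` duration."""
    x = _check_waveform(x)
    n_ramp = int(round(ramp_ms / 1000.0 * sample_rate))
    if x.size <= 2 * n_ramp:
        raise ValueError(
            f"clip of {x.size} samples shorter than two {n_ramp}-sample ramps"
        )
    y = x.copy()
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        y[:n_ramp] *= ramp
        y[-n_ramp:] *= ramp[::-1]
    return y


def ramp_and_scale(x, sample_rate: float, target_rms: float, ramp_ms: float = 10.0) -> Waveform:
    """Raised-cosine ramps followed by exact scaling to ``target_rms``."""
    y = apply_ramps(x, sample_rate, ramp_ms)
    r = rms(y)
    if r == 0:
        raise ValueError("cannot scale an all-zero clip to a nonzero RMS")
    return y * (target_rms / r)
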