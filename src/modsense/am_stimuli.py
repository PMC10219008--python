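"""Sinusoidally amplitude-modulated noise stimuli.

Generates the stimuli of the six psychophysical AM-detection conditions
(narrowband carriers of 2, 3, 31 and 314 Hz bandwidth plus short and long
broadband carriers) and the fully modulated broadband probes used for
simulated neurophysiology.

A sound with AM depth ``m`` (dB) and rate ``f`` (Hz) is

    y(t) = (1 + 10^(m/20) * sin(2*pi*f*t + phi)) * C(t)

where ``C(t)`` is a Gaussian-noise carrier sampled independently for every
stimulus and ``phi`` the AM starting phase (fixed at zero or drawn uniformly
per stimulus, depending on the condition).  Depth is expressed in dB relative
to the carrier amplitude, so ``m = 0`` is full modulation and ``m = -inf``
is an unmodulated carrier.

Each condition fixes the processing order of bandpass filtering and RMS
equalization relative to the modulation step: the 314 Hz-bandwidth condition
bandpasses *after* modulation, the other narrowband conditions before; the
short broadband condition equalizes the amplitude *before* modulation (so
its RMS grows with depth by the factor sqrt(1 + a^2/2)), all others after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .signal_ops import (
    apply_ramps,
    bandpass_fft,
    ramp_and_scale,
    rms,
)

__all__ = [
    "AmSpec",
    "AmConditionSpec",
    "apply_am",
    "make_stimulus",
    "neurophys_probe_set",
    "standard_conditions",
    "CONDITION_NAMES",
]

Waveform = NDArray[np.float64]

CONDITION_NAMES = (
    "2hz",
    "3hz",
    "31hz",
    "314hz",
    "broadband_short",
    "broadband_long",
)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# AM application
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmSpec:
    """One sinusoidal amplitude modulation applied to a carrier.

    ``depth_db`` <= 0 (``-inf`` means unmodulated); the linear modulation
    index is ``10^(depth_db/20)`` in (0, 1].
    """

    depth_db: float
    rate_hz: float
    phase: float
    carrier: Waveform
    sample_rate: float

    def __post_init__(self):
        if self.depth_db > 0:
            raise ValueError(f"AM depth must be <= 0 dB, got {self.depth_db}")
        if self.rate_hz <= 0:
            raise ValueError(f"AM rate must be positive, got {self.rate_hz}")
        if self.rate_hz >= self.sample_rate / 2:
            raise ValueError(
                f"AM rate {self.rate_hz} Hz at or above Nyquist "
                f"{self.sample_rate / 2} Hz"
            )

    @property
    def index(self) -> float:
        """Linear modulation index a = 10^(m/20)."""
        return float(10.0 ** (self.depth_db / 20.0))


def apply_am(spec: AmSpec) -> Waveform:
    """Modulate the carrier: (1 + a*sin(2*pi*f*t + phi)) * C(t)."""
    c = np.asarray(spec.carrier, dtype=float)
    t = np.arange(c.size) / spec.sample_rate
    modulator = 1.0 + spec.index * np.sin(2.0 * np.pi * spec.rate_hz * t + spec.phase)
    return modulator * c


# ---------------------------------------------------------------------------
# Psychophysical conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmConditionSpec:
    """Stimulus parameters of one AM-detection experiment.

    ``carrier_bandwidth_hz`` is ``None`` for a broadband carrier.  Depths
    span ``depth_range_db`` every ``depth_step_db`` dB and the eight test
    rates are evenly log-spaced in ``rate_range_hz``.
    """

    name: str
    carrier_bandwidth_hz: float | None
    duration_s: float
    phase_mode: str            # "fixed" | "random"
    equalize_order: str        # "before-AM" | "after-AM"
    bandpass_order: str        # "before-AM" | "after-AM" | "none"
    rate_range_hz: tuple[float, float]
    depth_range_db: tuple[float, float] = (-40.0, 0.0)
    center_freq_hz: float | None = None
    n_rates: int = 8
    depth_step_db: float = 4.0
    n_intervals: int = 2
    target_rms: float = 0.1
    sample_rate: float = 44100.0
    ramp_ms: float = 10.0

    def __post_init__(self):
        if self.phase_mode not in ("fixed", "random"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")
        if self.equalize_order not in ("before-AM", "after-AM"):
            raise ValueError(f"unknown equalize_order {self.equalize_order!r}")
        if self.bandpass_order not in ("before-AM", "after-AM", "none"):
            raise ValueError(f"unknown bandpass_order {self.bandpass_order!r}")
        if self.carrier_bandwidth_hz is not None and self.center_freq_hz is None:
            raise ValueError("narrowband condition needs a center frequency")
        if self.n_intervals not in (2, 3):
            raise ValueError("forced-choice tasks here use 2 or 3 intervals")

    @property
    def rates_hz(self) -> NDArray[np.float64]:
        """The eight AM rates, evenly spaced on a log scale."""
        lo, hi = self.rate_range_hz
        return np.geomspace(lo, hi, self.n_rates)

    @property
    def depths_db(self) -> NDArray[np.float64]:
        """Tested AM depths, every ``depth_step_db`` dB across the range."""
        lo, hi = self.depth_range_db
        n = int(round((hi - lo) / self.depth_step_db)) + 1
        return lo + self.depth_step_db * np.arange(n)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))

    def carrier_band(self) -> tuple[float, float]:
        bw = self.carrier_bandwidth_hz
        cf = self.center_freq_hz
        return (cf - bw / 2.0, cf + bw / 2.0)


def standard_conditions(
    sample_rate: float = 44100.0,
    center_freq_hz: float = 5000.0,
    target_rms: float = 0.1,
) -> dict[str, AmConditionSpec]:
    """The six built-in stimulus conditions.

    Bandwidth, duration, AM starting-phase mode and equalization order follow
    the human experiments being simulated; the per-condition AM rate ranges
    and the narrowband carrier center frequency are editable defaults chosen
    to span the rates used in those experiments (they are not uniquely fixed
    by the simulation procedure itself).
    """
    common = dict(sample_rate=sample_rate, target_rms=target_rms)
    nb = dict(center_freq_hz=center_freq_hz, bandpass_order="before-AM", **common)
    conds = [
        AmConditionSpec(
            name="2hz", carrier_bandwidth_hz=2.0, duration_s=2.0,
            phase_mode="random", equalize_order="after-AM",
            rate_range_hz=(2.0, 64.0), depth_range_db=(-60.0, 0.0),
            n_intervals=2, **nb,
        ),
        AmConditionSpec(
            name="3hz", carrier_bandwidth_hz=3.0, duration_s=1.0,
            phase_mode="fixed", equalize_order="after-AM",
            rate_range_hz=(3.0, 100.0), n_intervals=3, **nb,
        ),
        AmConditionSpec(
            name="31hz", carrier_bandwidth_hz=31.0, duration_s=1.0,
            phase_mode="fixed", equalize_order="after-AM",
            rate_range_hz=(3.0, 100.0), n_intervals=3, **nb,
        ),
        AmConditionSpec(
            name="314hz", carrier_bandwidth_hz=314.0, duration_s=1.0,
            phase_mode="fixed", equalize_order="after-AM",
            rate_range_hz=(4.0, 256.0), n_intervals=3,
            center_freq_hz=center_freq_hz, bandpass_order="after-AM", **common,
        ),
        AmConditionSpec(
            name="broadband_short", carrier_bandwidth_hz=None, duration_s=0.5,
            phase_mode="fixed", equalize_order="before-AM", bandpass_order="none",
            rate_range_hz=(4.0, 256.0), n_intervals=2, **common,
        ),
        AmConditionSpec(
            name="broadband_long", carrier_bandwidth_hz=None, duration_s=2.0,
            phase_mode="random", equalize_order="after-AM", bandpass_order="none",
            rate_range_hz=(2.0, 1024.0), n_intervals=2, **common,
        ),
    ]
    return {c.name: c for c in conds}


def make_stimulus(
    cond: AmConditionSpec,
    rate_hz: float,
    depth_db: float,
    modulated: bool,
    rng_seed,
) -> Waveform:
    """Generate one stimulus interval for a condition.

    The Gaussian-noise carrier is sampled independently per stimulus.  The
    pipeline honours the condition's bandpass and equalization orders; ramps
    are always applied last, with exact re-scaling to ``target_rms`` in
    equalize-after-AM conditions.
    """
    if rate_hz >= cond.sample_rate / 2:
        raise ValueError(f"AM rate {rate_hz} Hz at or above Nyquist")
    rng = _as_rng(rng_seed)
    x = rng.standard_normal(cond.n_samples)

    if cond.bandpass_order == "before-AM" and cond.carrier_bandwidth_hz is not None:
        lo, hi = cond.carrier_band()
        x = bandpass_fft(x, lo, hi, cond.sample_rate)
    if cond.equalize_order == "before-AM":
        x = x * (cond.target_rms / rms(x))

    if modulated:
        phase = 0.0 if cond.phase_mode == "fixed" else float(rng.uniform(0, 2 * np.pi))
        x = apply_am(AmSpec(depth_db=depth_db, rate_hz=rate_hz, phase=phase,
                            carrier=x, sample_rate=cond.sample_rate))

    if cond.bandpass_order == "after-AM" and cond.carrier_bandwidth_hz is not None:
        lo, hi = cond.carrier_band()
        x = bandpass_fft(x, lo, hi, cond.sample_rate)

    if cond.equalize_order == "after-AM":
        return ramp_and_scale(x, cond.sample_rate, cond.target_rms, cond.ramp_ms)
    return apply_ramps(x, cond.sample_rate, cond.ramp_ms)


# ---------------------------------------------------------------------------
# Neurophysiological probes
# ---------------------------------------------------------------------------

def neurophys_probe_set(
    rates_hz,
    sample_rate: float,
    duration_s: float,
    n_repeats: int,
    rng_seed,
    target_rms: float = 0.1,
) -> dict[float, list[Waveform]]:
    """Fully modulated (0 dB depth) broadband white-noise probes.

    Returns ``{rate: [waveform, ...]}`` with an independent carrier per
    repeat; used to measure AM tuning curves unit by unit.
    """
    rng = _as_rng(rng_seed)
    n = int(round(duration_s * sample_rate))
    out: dict[float, list[Waveform]] = {}
    for rate in rates_hz:
        if rate <= 0 or rate >= sample_rate / 2:
            raise ValueError(f"probe rate {rate} Hz outside (0, Nyquist)")
        reps = []
        for _ in range(n_repeats):
            carrier = rng.standard_normal(n)
            y = apply_am(AmSpec(depth_db=0.0, rate_hz=float(rate), phase=0.0,
                                carrier=carrier, sample_rate=sample_rate))
            reps.append(ramp_and_scale(y, sample_rate, target_rms))
        out[float(rate)] = reps
    return out
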