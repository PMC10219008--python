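"""Simulated forced-choice AM-detection experiments.

Measures temporal modulation transfer functions (TMTFs) on a frozen
recognizer layer by layer.  In each x-interval forced-choice (xIFC) trial,
x stimuli are generated with independent carriers, exactly one of them
modulated; a detector reads the layer's unit activities and names the
modulated interval.  Two detectors are provided:

* ``logistic`` — the time-averaged activity of every unit in the layer is
  the feature vector; an L2-regularized logistic regression is trained to
  discriminate modulated from unmodulated stimuli in a 4-fold outer
  cross-validation over trials (the L2 strength is chosen in an inner 4-fold
  CV), and the response is the interval with the maximum modulated
  probability.
* ``template`` — the response is the interval whose unit-by-time activity
  has the largest dot product with a template (mean activity to fully
  modulated stimuli minus mean activity to unmodulated stimuli).

The proportion of correct trials per AM depth (constant-stimulus method,
128 trials per depth) is fitted with an asymmetric sigmoid, and the
detection threshold is the depth at which the fitted curve crosses 70.7%
correct; thresholds outside the tested depth range are clipped to its
endpoints and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.optimize import brentq, least_squares
from sklearn.linear_model import LogisticRegressionCV

from .am_stimuli import AmConditionSpec, make_stimulus

__all__ = [
    "Trial",
    "PsychometricData",
    "PsychometricFit",
    "Template",
    "Tmtf",
    "LayerObserver",
    "make_trials",
    "trial_folds",
    "run_xifc_logistic",
    "make_template",
    "run_xifc_template",
    "fit_psychometric",
    "measure_tmtf",
    "THRESHOLD_CRITERION",
    "L2_GRID",
]

#: proportion-correct criterion defining the detection threshold
THRESHOLD_CRITERION = 0.707

#: inverse-regularization grid for the inner CV of the logistic detector;
#: ties resolve to the strongest regularization (smallest C)
L2_GRID = np.logspace(-3, 3, 13)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Observers
# ---------------------------------------------------------------------------

class LayerObserver:
    """Adapter exposing one frozen model layer to the detectors.

    Any object with an ``activations(waveform) -> unit x time array`` method
    can stand in for it (tests use hand-constructed observers).
    """

    def __init__(self, model, layer_index: int):
        self.model = model
        self.layer_index = int(layer_index)

    def activations(self, waveform) -> np.ndarray:
        _, recorded = self.model.forward(waveform, record_layers=(self.layer_index,))
        return recorded[0].activity


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One forced-choice trial: x stimuli, exactly one modulated."""

    stimuli: list
    modulated_index: int
    condition: str
    rate_hz: float
    depth_db: float

    def __post_init__(self):
        if not 0 <= self.modulated_index < len(self.stimuli):
            raise ValueError("modulated_index outside the interval list")


def make_trials(cond: AmConditionSpec, rate_hz: float, depth_db: float,
                n_trials: int, rng) -> list[Trial]:
    """Generate xIFC trials with independent carriers in every interval."""
    rng = _as_rng(rng)
    trials = []
    for _ in range(n_trials):
        mod_idx = int(rng.integers(cond.n_intervals))
        stimuli = [
            make_stimulus(cond, rate_hz, depth_db, modulated=(i == mod_idx), rng_seed=rng)
            for i in range(cond.n_intervals)
        ]
        trials.append(Trial(stimuli, mod_idx, cond.name, rate_hz, depth_db))
    return trials


def _argmax_with_ties(values: np.ndarray, rng) -> int:
    best = np.flatnonzero(values >= values.max() - 1e-12)
    return int(best[0] if best.size == 1 else rng.choice(best))


# ---------------------------------------------------------------------------
# Logistic detector
# ---------------------------------------------------------------------------

def trial_folds(n_trials: int, n_folds: int, rng) -> np.ndarray:
    """Assign trials to equal-size outer CV folds (seeded permutation).

    Returns an array mapping trial index -> fold; with the defaults, 128
    trials fall into 4 folds of 32 held-out trials each.
    """
    if n_trials % n_folds:
        raise ValueError(f"{n_trials} trials not divisible into {n_folds} folds")
    rng = _as_rng(rng)
    order = rng.permutation(n_trials)
    fold_of = np.empty(n_trials, dtype=int)
    fold_of[order] = np.arange(n_trials) % n_folds
    return fold_of


def run_xifc_logistic(observer, cond: AmConditionSpec, rate_hz: float,
                      depth_db: float, n_trials: int = 128, rng_seed=0,
                      n_folds: int = 4) -> float:
    """Proportion correct of the time-average logistic detector.

    Outer ``n_folds``-fold CV over trials (all of a trial's intervals stay
    in the same fold); per fold, a logistic regression with inner-CV-selected
    L2 strength is trained on the training trials' time-averaged unit
    activities, and each held-out trial's response is the interval with the
    maximum modulated-probability.
    """
    rng = _as_rng(rng_seed)
    trials = make_trials(cond, rate_hz, depth_db, n_trials, rng)
    feats = np.array([
        observer.activations(s).mean(axis=1) for t in trials for s in t.stimuli
    ])
    x = cond.n_intervals
    labels = np.zeros(n_trials * x, dtype=int)
    for i, t in enumerate(trials):
        labels[i * x + t.modulated_index] = 1

    fold_of = trial_folds(n_trials, n_folds, rng)

    correct = 0
    for fold in range(n_folds):
        train_t = np.flatnonzero(fold_of != fold)
        test_t = np.flatnonzero(fold_of == fold)
        train_s = np.concatenate([np.arange(i * x, (i + 1) * x) for i in train_t])
        mu = feats[train_s].mean(axis=0)
        sd = feats[train_s].std(axis=0)
        sd[sd < 1e-12] = 1.0
        clf = LogisticRegressionCV(
            Cs=L2_GRID, cv=n_folds, l1_ratios=(0.0,), scoring="accuracy",
            max_iter=2000, use_legacy_attributes=False,
            random_state=int(rng.integers(2**31)),
        )
        clf.fit((feats[train_s] - mu) / sd, labels[train_s])
        for i in test_t:
            rows = (feats[np.arange(i * x, (i + 1) * x)] - mu) / sd
            p_mod = clf.predict_proba(rows)[:, 1]
            if _argmax_with_ties(p_mod, rng) == trials[i].modulated_index:
                correct += 1
    return correct / n_trials


# ---------------------------------------------------------------------------
# Template detector
# ---------------------------------------------------------------------------

@dataclass
class Template:
    """Unit x time template: mean response to fully modulated stimuli minus
    mean response to unmodulated stimuli."""

    layer_index: int
    values: NDArray[np.float64]


def make_template(observer, cond: AmConditionSpec, rate_hz: float,
                  n: int = 128, rng_seed=0, layer_index: int = 0) -> Template:
    """Build the detector template from ``n`` independent fully modulated and
    ``n`` unmodulated stimuli."""
    rng = _as_rng(rng_seed)
    mod = np.mean([
        observer.activations(make_stimulus(cond, rate_hz, 0.0, True, rng))
        for _ in range(n)
    ], axis=0)
    unmod = np.mean([
        observer.activations(make_stimulus(cond, rate_hz, 0.0, False, rng))
        for _ in range(n)
    ], axis=0)
    idx = getattr(observer, "layer_index", layer_index)
    return Template(layer_index=idx, values=mod - unmod)


def run_xifc_template(observer, template: Template, cond: AmConditionSpec,
                      rate_hz: float, depth_db: float, n_trials: int = 128,
                      rng_seed=0) -> float:
    """Proportion correct of the template-correlation detector.

    The per-interval decision variable is the non-normalized correlation
    (dot product over units and time) with the template; ties break
    uniformly at random.
    """
    rng = _as_rng(rng_seed)
    trials = make_trials(cond, rate_hz, depth_db, n_trials, rng)
    correct = 0
    for t in trials:
        scores = []
        for s in t.stimuli:
            act = observer.activations(s)
            if act.shape != template.values.shape:
                raise ValueError(
                    f"activity shape {act.shape} does not match template "
                    f"shape {template.values.shape}"
                )
            scores.append(float(np.sum(act * template.values)))
        if _argmax_with_ties(np.asarray(scores), rng) == t.modulated_index:
            correct += 1
    return correct / n_trials


# ---------------------------------------------------------------------------
# Psychometric fitting
# ---------------------------------------------------------------------------

@dataclass
class PsychometricData:
    """Proportion correct per tested AM depth (n_trials trials each)."""

    depths_db: NDArray[np.float64]
    proportion_correct: NDArray[np.float64]
    n_trials: int = 128


@dataclass
class PsychometricFit:
    """An asymmetric sigmoid fitted to a psychometric curve:

        psi(m) = gamma + (1 - gamma) * (1 + exp(-(m - alpha)/beta))^(-lambda)

    with the guess rate gamma pinned to 1/x.  ``threshold_db`` is the depth
    at which psi crosses the 70.7% criterion, clipped to the tested range
    (and flagged) when the crossing lies outside it.
    """

    guess_rate: float
    alpha: float
    beta: float
    lam: float
    threshold_db: float
    clipped: bool
    converged: bool = True

    def predict(self, depth_db) -> np.ndarray:
        return _sigmoid(depth_db, self.guess_rate, self.alpha, self.beta, self.lam)


def _sigmoid(m, gamma, alpha, beta, lam):
    z = np.clip(-(np.asarray(m, dtype=float) - alpha) / beta, -500.0, 500.0)
    return gamma + (1 - gamma) * (1 + np.exp(z)) ** (-lam)


def fit_psychometric(data: PsychometricData, n_intervals: int) -> PsychometricFit:
    """Least-squares fit of the asymmetric sigmoid with multi-start.

    The fitted curve is non-decreasing in depth by construction (beta > 0,
    lambda > 0).  If the optimizer fails on every start, a degenerate fit is
    returned with ``converged=False`` and the threshold clipped according to
    the mean proportion correct.
    """
    depths = np.asarray(data.depths_db, dtype=float)
    props = np.asarray(data.proportion_correct, dtype=float)
    if depths.size < 4:
        raise ValueError("need at least 4 depth points to fit")
    if np.any((props < 0) | (props > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    gamma = 1.0 / n_intervals
    lo, hi = float(depths.min()), float(depths.max())

    def resid(theta):
        return _sigmoid(depths, gamma, *theta) - props

    best = None
    span = hi - lo
    for a0 in np.linspace(lo, hi, 5):
        for b0 in (span / 20, span / 6):
            for l0 in (0.5, 1.0, 2.0):
                try:
                    sol = least_squares(
                        resid, x0=[a0, b0, l0],
                        bounds=([lo - 2 * span, 1e-3, 1e-3],
                                [hi + 2 * span, 4 * span, 50.0]),
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
    if best is None:
        clipped_to = lo if props.mean() > THRESHOLD_CRITERION else hi
        return PsychometricFit(gamma, np.nan, np.nan, np.nan,
                               clipped_to, clipped=True, converged=False)

    alpha, beta, lam = best.x
    f = lambda m: _sigmoid(m, gamma, alpha, beta, lam) - THRESHOLD_CRITERION
    if f(lo) >= 0:          # curve above criterion over the whole range
        thr, clipped = lo, True
    elif f(hi) <= 0:        # curve below criterion over the whole range
        thr, clipped = hi, True
    else:
        thr, clipped = float(brentq(f, lo, hi, xtol=1e-6)), False
    return PsychometricFit(gamma, float(alpha), float(beta), float(lam),
                           thr, clipped)


# ---------------------------------------------------------------------------
# TMTF assembly
# ---------------------------------------------------------------------------

@dataclass
class Tmtf:
    """Detection thresholds (dB) at the condition's eight log-spaced rates."""

    condition: str
    rates_hz: NDArray[np.float64]
    thresholds_db: NDArray[np.float64]
    clipped: NDArray[np.bool_]
    layer_index: int
    detector: str

    def __post_init__(self):
        if len(self.rates_hz) != len(self.thresholds_db):
            raise ValueError("one threshold per rate required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "layer": self.layer_index, "condition": self.condition,
            "rate_hz": self.rates_hz, "threshold_db": self.thresholds_db,
            "clipped": self.clipped, "detector": self.detector,
        })


def measure_tmtf(observer, cond: AmConditionSpec, detector="logistic",
                 n_trials: int = 128, rng_seed=0, template_n: int = 128,
                 return_raw: bool = False):
    """Measure one layer's TMTF in one condition (constant-stimulus method).

    ``detector`` is ``"logistic"``, ``"template"`` or a callable
    ``(cond, rate_hz, depth_db, n_trials, rng) -> proportion_correct``
    (constructed observers in tests use the callable form).  One detector is
    built per (rate, depth); nothing is shared across depths.
    """
    layer_index = getattr(observer, "layer_index", 0)
    rates = cond.rates_hz
    depths = cond.depths_db
    thresholds, clipped_flags, raw_rows = [], [], []
    for ri, rate in enumerate(rates):
        if detector == "template":
            rate_seed = np.random.SeedSequence((rng_seed, ri))
            template = make_template(observer, cond, rate, n=template_n,
                                     rng_seed=np.random.default_rng(rate_seed))
        props = np.empty(depths.size)
        for di, depth in enumerate(depths):
            rng = np.random.default_rng(np.random.SeedSequence((rng_seed, ri, di)))
            if callable(detector):
                props[di] = detector(cond, float(rate), float(depth), n_trials, rng)
            elif detector == "logistic":
                props[di] = run_xifc_logistic(observer, cond, float(rate),
                                              float(depth), n_trials, rng)
            elif detector == "template":
                props[di] = run_xifc_template(observer, template, cond,
                                              float(rate), float(depth),
                                              n_trials, rng)
            else:
                raise ValueError(f"unknown detector {detector!r}")
            raw_rows.append({"rate_hz": float(rate), "depth_db": float(depth),
                             "proportion_correct": props[di]})
        fit = fit_psychometric(PsychometricData(depths, props, n_trials),
                               cond.n_intervals)
        thresholds.append(fit.threshold_db)
        clipped_flags.append(fit.clipped)
    name = detector if isinstance(detector, str) else getattr(
        detector, "__name__", "custom")
    tmtf = Tmtf(cond.name, rates, np.asarray(thresholds),
                np.asarray(clipped_flags), layer_index, name)
    if return_raw:
        return tmtf, pd.DataFrame(raw_rows)
    return tmtf
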