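"""Layered dilated-convolution sound recognizer.

A fully convolutional network over raw waveforms: each layer is a 1-D
dilated convolution (stride 1, no padding) followed by an exponential linear
unit, and a final filter-size-one convolution produces per-time-step category
scores.  The receptive field, 1 + sum((k_i - 1) * d_i) over layers, is
constrained not to exceed the 0.2 s input window during architecture
sampling.

Training minimizes softmax cross-entropy computed at a single output time
step per example (a window exactly one receptive field long), using Adam
with early stopping on a held-out part of the training set.  After
optimization the model is frozen: the psychophysical and neurophysiological
simulations only ever read activations.

The implementation is pure numpy; forward and backward passes are written as
einsum contractions over strided views, which is ample for the network sizes
used here.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = [
    "Architecture",
    "TrainingConfig",
    "TrainedModel",
    "DilatedConvNet",
    "LayerActivations",
    "receptive_field",
    "sample_architecture",
    "train",
    "evaluate_recognition",
    "architecture_search",
    "chance_level",
    "REFERENCE_ARCHITECTURES",
    "ALLOWED_N_LAYERS",
    "ALLOWED_UNITS",
]

ALLOWED_N_LAYERS = (7, 9, 11, 13)
ALLOWED_UNITS = (32, 64, 128, 256, 512)
FILTER_SIZE_RANGE = (2, 8)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Architecture:
    """Hyperparameters of one network: per-layer filter sizes and dilations,
    a uniform unit count, and the input window the receptive field must fit."""

    n_layers: int
    units_per_layer: int
    filter_sizes: tuple[int, ...]
    dilations: tuple[int, ...]
    n_categories: int
    input_window_samples: int

    def __post_init__(self):
        if len(self.filter_sizes) != self.n_layers or len(self.dilations) != self.n_layers:
            raise ValueError("filter_sizes and dilations must have n_layers entries")
        if any(k < 1 for k in self.filter_sizes) or any(d < 1 for d in self.dilations):
            raise ValueError("filter sizes and dilations must be positive")
        if receptive_field(self) > self.input_window_samples:
            raise ValueError(
                f"receptive field {receptive_field(self)} exceeds the input "
                f"window of {self.input_window_samples} samples"
            )

    def to_json(self) -> str:
        return json.dumps({
            "n_layers": self.n_layers,
            "units_per_layer": self.units_per_layer,
            "filter_sizes": list(self.filter_sizes),
            "dilations": list(self.dilations),
            "n_categories": self.n_categories,
            "input_window_samples": self.input_window_samples,
        })

    @staticmethod
    def from_json(s: str) -> "Architecture":
        d = json.loads(s)
        return Architecture(
            n_layers=d["n_layers"], units_per_layer=d["units_per_layer"],
            filter_sizes=tuple(d["filter_sizes"]), dilations=tuple(d["dilations"]),
            n_categories=d["n_categories"],
            input_window_samples=d["input_window_samples"],
        )


def receptive_field(arch: Architecture) -> int:
    """Receptive field in samples: 1 + sum((filter_size - 1) * dilation)."""
    ks, ds = arch.filter_sizes, arch.dilations
    if len(ks) != len(ds):
        raise ValueError("per-layer lists must have the same length")
    if any(k < 1 for k in ks) or any(d < 1 for d in ds):
        raise ValueError("filter sizes and dilations must be positive")
    return 1 + int(sum((k - 1) * d for k, d in zip(ks, ds)))


def _reference_arch(units, filters, dilations):
    return Architecture(
        n_layers=13, units_per_layer=units, filter_sizes=tuple(filters),
        dilations=tuple(dilations), n_categories=50, input_window_samples=8820,
    )


#: Four published 13-layer architectures for the 44.1 kHz everyday-sound
#: recognizer; all satisfy the 0.2 s (8820-sample) receptive-field bound.
#: Used as fixtures and worked examples, never retrained here at full scale.
REFERENCE_ARCHITECTURES = (
    _reference_arch(256, (5, 3, 6, 5, 2, 7, 8, 8, 7, 4, 4, 6, 5),
                    (231, 603, 18, 138, 14, 97, 105, 7, 137, 381, 193, 208, 266)),
    _reference_arch(512, (3, 4, 4, 3, 6, 6, 4, 6, 8, 8, 7, 7, 3),
                    (449, 12, 161, 374, 175, 193, 120, 209, 161, 47, 151, 16, 465)),
    _reference_arch(128, (7, 4, 4, 2, 7, 3, 7, 5, 2, 4, 3, 7, 2),
                    (42, 125, 341, 603, 96, 410, 44, 269, 747, 152, 528, 122, 823)),
    _reference_arch(512, (3, 7, 2, 7, 7, 4, 5, 5, 3, 8, 8, 8, 2),
                    (676, 105, 581, 54, 16, 192, 214, 2, 173, 173, 184, 92, 887)),
)


def sample_architecture(
    n_layers: int,
    input_window_samples: int,
    rng_seed,
    n_categories: int = 50,
    units_per_layer: int | None = None,
    filter_size_range: tuple[int, int] = FILTER_SIZE_RANGE,
) -> Architecture:
    """Randomly sample filter sizes and dilations under the receptive-field
    constraint.

    Filter sizes are uniform in ``filter_size_range``; each dilation is then
    drawn uniformly up to the largest value that still leaves every remaining
    layer at least dilation one, so the constraint holds by construction.
    Deterministic for a fixed seed.
    """
    if n_layers not in ALLOWED_N_LAYERS:
        raise ValueError(f"n_layers must be one of {ALLOWED_N_LAYERS}, got {n_layers}")
    rng = _as_rng(rng_seed)
    k_lo, k_hi = filter_size_range
    filters = rng.integers(k_lo, k_hi + 1, size=n_layers)
    min_needed = int(np.sum(filters - 1))  # all dilations = 1
    if min_needed + 1 > input_window_samples:
        raise ValueError(
            f"window of {input_window_samples} samples cannot fit {n_layers} "
            f"layers at minimum dilation"
        )
    budget = input_window_samples - 1
    dilations = np.empty(n_layers, dtype=int)
    for i in range(n_layers):
        reserve = int(np.sum(filters[i + 1:] - 1))  # later layers at dilation 1
        d_max = (budget - reserve) // (filters[i] - 1)
        dilations[i] = int(rng.integers(1, d_max + 1))
        budget -= (filters[i] - 1) * dilations[i]
    units = units_per_layer
    if units is None:
        units = int(rng.choice(ALLOWED_UNITS))
    elif units not in ALLOWED_UNITS:
        raise ValueError(f"units_per_layer must be one of {ALLOWED_UNITS}")
    return Architecture(
        n_layers=n_layers, units_per_layer=units,
        filter_sizes=tuple(int(k) for k in filters),
        dilations=tuple(int(d) for d in dilations),
        n_categories=n_categories, input_window_samples=input_window_samples,
    )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class LayerActivations:
    """Unit x time activity of one layer for one stimulus.  Time extent is
    the stimulus length minus the receptive-field trim up to that layer."""

    layer_index: int            # 1-based; the classification layer is never recorded
    activity: NDArray[np.float64]
    stimulus_id: str = ""


def _elu(z: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return np.where(z > 0, z, alpha * np.expm1(np.minimum(z, 0.0)))


def _elu_grad_from_act(a: np.ndarray, z: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return np.where(z > 0, 1.0, a + alpha)


def _conv_forward(h: np.ndarray, W: np.ndarray, b: np.ndarray, d: int) -> np.ndarray:
    """Valid dilated convolution.  h: (B, C, T), W: (U, C, k) -> (B, U, T_out)."""
    B, C, T = h.shape
    U, _, k = W.shape
    t_out = T - (k - 1) * d
    if t_out < 1:
        raise ValueError("input shorter than the layer's receptive field")
    v = np.stack([h[:, :, j * d: j * d + t_out] for j in range(k)])  # (k, B, C, T_out)
    return np.einsum("uck,kbct->but", W, v, optimize=True) + b[None, :, None]


def _conv_backward(h, W, d, dy):
    """Gradients of the valid dilated convolution."""
    B, C, T = h.shape
    U, _, k = W.shape
    t_out = dy.shape[2]
    v = np.stack([h[:, :, j * d: j * d + t_out] for j in range(k)])
    dW = np.einsum("but,kbct->uck", dy, v, optimize=True)
    db = dy.sum(axis=(0, 2))
    dh = np.zeros_like(h)
    for j in range(k):
        dh[:, :, j * d: j * d + t_out] += np.einsum(
            "uc,but->bct", W[:, :, j], dy, optimize=True
        )
    return dW, db, dh


class DilatedConvNet:
    """The recognizer: a stack of dilated convolutions with ELU activations
    topped by a filter-size-one classification convolution.

    Weights are fan-in-scaled uniform at initialization; biases start at
    zero ("nonoptimized model").  ``forward`` can record any convolutional
    layer's post-ELU activity; the classification layer is excluded from
    recording by construction.
    """

    ELU_ALPHA = 1.0

    def __init__(self, architecture: Architecture, rng_seed):
        rng = _as_rng(rng_seed)
        self.architecture = architecture
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        c_in = 1
        for k in architecture.filter_sizes:
            u = architecture.units_per_layer
            bound = np.sqrt(6.0 / (c_in * k))  # variance-preserving fan-in scaling
            self.weights.append(rng.uniform(-bound, bound, size=(u, c_in, k)))
            self.biases.append(np.zeros(u))
            c_in = u
        bound = np.sqrt(6.0 / c_in)
        self.w_cls = rng.uniform(-bound, bound, size=(architecture.n_categories, c_in, 1))
        self.b_cls = np.zeros(architecture.n_categories)

    # -- inference ----------------------------------------------------------

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.architecture)

    def forward(
        self,
        waveform,
        record_layers: tuple[int, ...] = (),
        stimulus_id: str = "",
    ) -> tuple[np.ndarray, list[LayerActivations]]:
        """Run one waveform through the network.

        Returns per-time-step category scores of shape (n_categories, T_out)
        and the requested layers' activations (1-based layer indices; the
        classification layer cannot be recorded).
        """
        arch = self.architecture
        bad = [l for l in record_layers if not 1 <= l <= arch.n_layers]
        if bad:
            raise ValueError(
                f"recordable layers are 1..{arch.n_layers} "
                f"(the classification layer is excluded); got {bad}"
            )
        x = np.asarray(waveform, dtype=float)
        if x.ndim != 1:
            raise ValueError("forward expects a single 1-D waveform")
        if x.size < self.receptive_field:
            raise ValueError(
                f"waveform of {x.size} samples shorter than the receptive "
                f"field of {self.receptive_field}"
            )
        h = x[None, None, :]
        recorded = []
        for i, (W, b, d) in enumerate(zip(self.weights, self.biases, arch.dilations), start=1):
            h = _elu(_conv_forward(h, W, b, d), self.ELU_ALPHA)
            if i in record_layers:
                recorded.append(LayerActivations(i, h[0].copy(), stimulus_id))
        scores = _conv_forward(h, self.w_cls, self.b_cls, 1)[0]
        return scores, recorded

    def _forward_train(self, xb: np.ndarray):
        """Batched forward on windows (B, RF); caches pre-ELU inputs."""
        h = xb[:, None, :]
        cache = []
        for W, b, d in zip(self.weights, self.biases, self.architecture.dilations):
            z = _conv_forward(h, W, b, d)
            a = _elu(z, self.ELU_ALPHA)
            cache.append((h, z, a))
            h = a
        scores = _conv_forward(h, self.w_cls, self.b_cls, 1)
        return scores, cache, h

    def _backward_train(self, xb, labels, cache, top, scores):
        """Softmax cross-entropy gradient at the single output time step."""
        B = xb.shape[0]
        logits = scores[:, :, 0]
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(p[np.arange(B), labels] + 1e-300))
        dlogits = p
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        dy = dlogits[:, :, None]
        dWc, dbc, dh = _conv_backward(top, self.w_cls, 1, dy)
        grads_w, grads_b = [dWc], [dbc]
        for (h, z, a), W, d in zip(reversed(cache), reversed(self.weights),
                                   reversed(self.architecture.dilations)):
            dz = dh * _elu_grad_from_act(a, z, self.ELU_ALPHA)
            dW, db, dh = _conv_backward(h, W, d, dz)
            grads_w.append(dW)
            grads_b.append(db)
        grads_w.reverse()
        grads_b.reverse()
        return loss, grads_w, grads_b

    # -- bookkeeping --------------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, self.w_cls, *self.biases, self.b_cls]

    def param_checksum(self) -> float:
        """Cheap fingerprint used to verify the freeze contract."""
        return float(sum(np.sum(np.abs(p)) for p in self.parameters()))

    def copy(self) -> "DilatedConvNet":
        return copy.deepcopy(self)

    def save(self, path):
        """Single-file checkpoint: architecture JSON + weight arrays."""
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        arrays |= {"w_cls": self.w_cls, "b_cls": self.b_cls}
        np.savez(path, arch=np.frombuffer(self.architecture.to_json().encode(), dtype=np.uint8),
                 **arrays)

    @staticmethod
    def load(path) -> "DilatedConvNet":
        with np.load(path) as data:
            arch = Architecture.from_json(bytes(data["arch"]).decode())
            net = DilatedConvNet(arch, rng_seed=0)
            net.weights = [data[f"w{i}"] for i in range(arch.n_layers)]
            net.biases = [data[f"b{i}"] for i in range(arch.n_layers)]
            net.w_cls = data["w_cls"]
            net.b_cls = data["b_cls"]
        return net


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimizer and regimen settings.

    ``amplitude_jitter_db`` scales each training clip by a uniform random
    gain in +/- that many dB (training only; evaluation uses unit gain).
    """

    learning_rate: float = 1e-4
    patience_epochs: int = 8
    batch_size: int = 16
    amplitude_jitter_db: float = 6.0
    max_epochs: int = 300
    windows_per_clip: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")


@dataclass
class TrainedModel:
    """A frozen recognizer plus its training log (per-epoch early-stop
    accuracy).  Simulated experiments never mutate the parameters."""

    net: DilatedConvNet
    training_log: pd.DataFrame
    frozen: bool = True

    @property
    def architecture(self) -> Architecture:
        return self.net.architecture

    @property
    def best_accuracy(self) -> float:
        if len(self.training_log) == 0:
            return float("nan")
        return float(self.training_log["early_stop_accuracy"].max())

    def forward(self, waveform, record_layers=(), stimulus_id=""):
        return self.net.forward(waveform, record_layers, stimulus_id)

    def param_checksum(self) -> float:
        return self.net.param_checksum()


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** self.t)
            vhat = v / (1 - beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _training_windows(clips, labels, rf, rng, jitter_db, windows_per_clip=1):
    """Random receptive-field-long windows per clip, amplitude-jittered."""
    idx = rng.permutation(np.repeat(np.arange(len(clips)), windows_per_clip))
    xs, ys = [], []
    for i in idx:
        clip = clips[i]
        start = int(rng.integers(0, clip.size - rf + 1))
        gain = 10.0 ** (rng.uniform(-jitter_db, jitter_db) / 20.0)
        xs.append(gain * clip[start:start + rf])
        ys.append(labels[i])
    return np.asarray(xs), np.asarray(ys)


def train(
    net: DilatedConvNet,
    update_clips,
    update_labels,
    early_stop_clips,
    early_stop_labels,
    config: TrainingConfig,
) -> TrainedModel:
    """Optimize a network for clip classification with early stopping.

    One epoch is a pass over the update split (one random window per clip,
    batched).  After each epoch, whole-clip accuracy on the early-stop split
    is computed; training stops when it has not improved for
    ``patience_epochs`` epochs, and the parameters of the best epoch are
    returned frozen.
    """
    if len(update_clips) == 0 or len(early_stop_clips) == 0:
        raise ValueError("update and early-stop splits must be nonempty")
    rng = _as_rng(config.rng_seed)
    rf = net.receptive_field
    if any(c.size < rf for c in update_clips):
        raise ValueError("all training clips must be at least one receptive field long")

    params = [*net.weights, net.w_cls]
    bias_params = [*net.biases, net.b_cls]
    opt = _Adam(params + bias_params, config.learning_rate)

    best_acc, best_state, since_best = -np.inf, None, 0
    log_rows = []
    labels_u = np.asarray(update_labels)
    labels_e = np.asarray(early_stop_labels)
    for epoch in range(config.max_epochs):
        xs, ys = _training_windows(update_clips, labels_u, rf, rng,
                                   config.amplitude_jitter_db,
                                   config.windows_per_clip)
        losses = []
        for s in range(0, len(xs), config.batch_size):
            xb, yb = xs[s:s + config.batch_size], ys[s:s + config.batch_size]
            scores, cache, top = net._forward_train(xb)
            loss, gw, gb = net._backward_train(xb, yb, cache, top, scores)
            opt.step(params + bias_params, gw + gb)
            losses.append(loss)
        acc = evaluate_recognition(net, early_stop_clips, labels_e)
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                         "early_stop_accuracy": acc})
        if acc > best_acc:
            best_acc, since_best = acc, 0
            best_state = copy.deepcopy((net.weights, net.biases, net.w_cls, net.b_cls))
        else:
            since_best += 1
            if since_best >= config.patience_epochs:
                break
    if best_state is not None:
        net.weights, net.biases, net.w_cls, net.b_cls = best_state
    return TrainedModel(net=net, training_log=pd.DataFrame(log_rows))


def chance_level(n_categories: int) -> float:
    """Accuracy of uniform-random classification over balanced categories."""
    if n_categories < 1:
        raise ValueError("need at least one category")
    return 1.0 / n_categories


def evaluate_recognition(net, clips, labels, segment_spans=None) -> float:
    """Fraction of clips classified correctly after time-averaging the
    classification-layer output (optionally over per-clip segment spans,
    e.g. phoneme intervals expressed in output-frame indices)."""
    if hasattr(net, "net"):  # accept a TrainedModel
        net = net.net
    labels = np.asarray(labels)
    if len(clips) != len(labels):
        raise ValueError("clips and labels must have equal length")
    correct = 0
    total = 0
    for i, clip in enumerate(clips):
        scores, _ = net.forward(clip)
        spans = [(0, scores.shape[1])] if segment_spans is None else segment_spans[i]
        for lo, hi in spans:
            if not 0 <= lo < hi <= scores.shape[1]:
                raise ValueError(f"span ({lo}, {hi}) outside clip output of "
                                 f"{scores.shape[1]} frames")
            pred = int(np.argmax(scores[:, lo:hi].mean(axis=1)))
            label = labels[i] if np.ndim(labels[i]) == 0 else labels[i][total]
            correct += int(pred == label)
            total += 1
    return correct / total


# ---------------------------------------------------------------------------
# Two-step architecture search
# ---------------------------------------------------------------------------

def architecture_search(
    update_clips, update_labels, early_stop_clips, early_stop_labels,
    input_window_samples: int,
    n_categories: int,
    rng_seed,
    n_layers_options=ALLOWED_N_LAYERS,
    n_candidates: int = 20,
    best_k: int = 4,
    patience_step1: int = 32,
    patience_step2: int = 96,
    config: TrainingConfig | None = None,
    units_per_layer: int | None = None,
    candidates: dict[int, list[Architecture]] | None = None,
) -> list[TrainedModel]:
    """Two-step search over randomly sampled architectures.

    Step 1 trains ``n_candidates`` models per layer count with the smaller
    patience and ranks the layer counts by the mean accuracy of their
    ``best_k`` best models.  Step 2 retrains the winning layer count's
    candidates with the larger patience and returns its ``best_k`` best
    models (sorted, best first).  ``candidates`` may supply pre-chosen
    architectures per layer count instead of random sampling.
    """
    base = config or TrainingConfig()
    rng = _as_rng(rng_seed)

    def _run(arch, patience, seed):
        cfg = dataclasses.replace(base, patience_epochs=patience, rng_seed=seed)
        net = DilatedConvNet(arch, rng_seed=seed)
        return train(net, update_clips, update_labels,
                     early_stop_clips, early_stop_labels, cfg)

    if candidates is None:
        if n_candidates < best_k:
            raise ValueError(f"need at least best_k={best_k} candidates per layer count")
        candidates = {
            nl: [sample_architecture(nl, input_window_samples, rng, n_categories,
                                     units_per_layer=units_per_layer)
                 for _ in range(n_candidates)]
            for nl in n_layers_options
        }
    elif any(len(v) < best_k for v in candidates.values()):
        raise ValueError(f"need at least best_k={best_k} candidates per layer count")
    step1_scores = {}
    for nl, archs in candidates.items():
        models = [_run(a, patience_step1, int(rng.integers(2**31))) for a in archs]
        accs = sorted((m.best_accuracy for m in models), reverse=True)
        step1_scores[nl] = float(np.mean(accs[:best_k]))
    winner = max(step1_scores, key=step1_scores.get)

    finalists = [_run(a, patience_step2, int(rng.integers(2**31)))
                 for a in candidates[winner]]
    finalists.sort(key=lambda m: m.best_accuracy, reverse=True)
    return finalists[:best_k]
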