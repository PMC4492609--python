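"""Delay-response loss, backpropagation through time, and the SGD loop.

Supervision follows the delay-response scheme: the target distribution is
compared with the network output only during the d black frames appended
after the visual stream, via the Kullback-Leibler divergence

    E = sum_t E_t,   E_t = KL(y* || y_t) on supervised steps, else 0,

which for a one-hot target reduces to -ln y_t[c].  Gradients are computed
by unrolling the leaky-integrator recursion over all T steps (the
(1 - 1/tau) carry propagates error backward in time), routed through the
scaled-tanh derivative, pooling argmax positions, and kernel weight
sharing, then normalized by the sequence length T.  Updates are plain
per-sequence SGD with a 0.0005 weight decay on kernel and output weights
(never on biases) and a bold-driver learning-rate schedule (x1.05 on
epoch-error decrease, /2 otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .architecture import ArchitectureSpec
from .network import (
    Parameters,
    conv_input_grad,
    conv_kernel_grad,
    forward_sequence,
    max_unpool,
    parameter_shapes,
    scaled_tanh_deriv,
    zero_parameters,
)

PROB_FLOOR = 1e-12  # floor inside ln() so collapsed outputs give a large, finite loss
WEIGHT_DECAY = 0.0005


class TrainingDiverged(RuntimeError):
    """Raised when a loss or gradient becomes non-finite."""


# ---------------------------------------------------------------------------
# targets and loss


def one_hot(label: int, n_classes: int) -> np.ndarray:
    """One-hot target distribution y*: 1 at the true class, 0 elsewhere."""
    if not 0 <= label < n_classes:
        raise ValueError(f"label {label} out of range for {n_classes} classes")
    y = np.zeros(n_classes)
    y[label] = 1.0
    return y


def supervised_mask(T: int, d: int, window: str = "final") -> np.ndarray:
    """Boolean mask of supervised steps (0-based indices over T steps).

    ``window="final"``: the final d steps (the prose reading).
    ``window="literal"``: steps with T - t <= d for 1-based t, which
    covers d + 1 steps.
    """
    if not 1 <= d <= T:
        raise ValueError(f"need 1 <= d <= T, got d={d}, T={T}")
    mask = np.zeros(T, dtype=bool)
    if window == "final":
        mask[T - d :] = True
    elif window == "literal":
        mask[max(T - d - 1, 0) :] = True
    else:
        raise ValueError(f"unknown window {window!r}")
    return mask


@dataclass
class LossLedger:
    """Per-step errors, the supervised-step mask, and the total."""

    per_step: np.ndarray
    mask: np.ndarray
    total: float
    T: int
    d: int


def sequence_loss(outputs, target, d: int, window: str = "final") -> LossLedger:
    """Delay-response KL loss of a (T, C) output trace against a one-hot
    (or any normalized) target distribution."""
    Y = np.asarray(outputs, dtype=float)
    ystar = np.asarray(target, dtype=float)
    T = Y.shape[0]
    mask = supervised_mask(T, d, window)
    per_step = np.zeros(T)
    pos = ystar > 0
    for t in np.flatnonzero(mask):
        per_step[t] = float(
            np.sum(ystar[pos] * np.log(ystar[pos] / np.maximum(Y[t, pos], PROB_FLOOR)))
        )
    return LossLedger(per_step=per_step, mask=mask, total=float(per_step.sum()), T=T, d=d)


# ---------------------------------------------------------------------------
# gradients


@dataclass
class GradientSet:
    """Gradients shaped like :class:`Parameters`, already normalized by
    the sequence length T used to compute them."""

    kernels: list
    conv_biases: list
    head_weight: np.ndarray
    head_bias: np.ndarray
    T: int

    def all_finite(self) -> bool:
        ok = all(np.isfinite(k).all() for k in self.kernels)
        ok = ok and all(np.isfinite(b).all() for b in self.conv_biases)
        return bool(
            ok
            and np.isfinite(self.head_weight).all()
            and np.isfinite(self.head_bias).all()
        )


def backprop_through_time(
    frames,
    label: int,
    params: Parameters,
    spec: ArchitectureSpec,
    d: int,
    window: str = "final",
):
    """Exact gradient of the delay-response loss over one sequence.

    ``frames`` must already carry its appended black frames.  Returns
    (grads, ledger, Y): the T-normalized :class:`GradientSet`, the loss
    ledger, and the (T, C) output trace of the forward pass.
    """
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    Y, cache = forward_sequence(params, spec, frames, cache=True)
    ystar = one_hot(label, spec.n_classes)
    ledger = sequence_loss(Y, ystar, d, window)

    conv_pos = spec.conv_indices
    n_conv = len(conv_pos)
    taus = [spec.layers[i].tau for i in conv_pos]
    shapes = parameter_shapes(spec)
    g = GradientSet(
        kernels=[np.zeros(s) for s in shapes["kernels"]],
        conv_biases=[np.zeros(s) for s in shapes["conv_biases"]],
        head_weight=np.zeros(shapes["head_weight"]),
        head_bias=np.zeros(shapes["head_bias"]),
        T=T,
    )
    # gradient w.r.t. u_{t+1} of each conv layer, carried backward in time
    gu_next = [np.zeros(spec.layers[i].maps * spec.layers[i].rows * spec.layers[i].cols)
               .reshape(spec.layers[i].maps, spec.layers[i].rows, spec.layers[i].cols)
               for i in conv_pos]

    hidden = spec.hidden
    top_shape = cache.U[-1].shape[1:]
    for t in range(T - 1, -1, -1):
        if ledger.mask[t]:
            ds = Y[t] - ystar  # d(-ln y_c)/ds for softmax outputs
            g.head_weight += np.outer(ds, cache.head_in[t])
            g.head_bias += ds
            g_head = params.head_weight.T @ ds
        else:
            g_head = None

        # walk the hidden stack top-down, pushing the activation gradient
        g_v = None  # gradient w.r.t. current layer's output at step t
        g_u_extra = None  # head gradient injected directly into top-layer u
        if g_head is not None:
            if spec.head_reads == "internal":
                g_u_extra = g_head.reshape(top_shape)
            else:
                g_v = g_head.reshape(
                    hidden[-1].maps, hidden[-1].rows, hidden[-1].cols
                )
        ci = n_conv - 1
        pi = len(cache.pool_idx) - 1
        for li in range(len(hidden) - 1, -1, -1):
            l = hidden[li]
            if l.role == "max_pooling":
                if g_v is not None:
                    prev = hidden[li - 1]
                    g_v = max_unpool(
                        g_v, cache.pool_idx[pi][t], l.pool, (l.maps, prev.rows, prev.cols)
                    )
                pi -= 1
            else:  # convolutional
                u_t = cache.U[ci][t]
                gu = (1.0 - 1.0 / taus[ci]) * gu_next[ci]
                if g_v is not None:
                    gu = gu + g_v * scaled_tanh_deriv(u_t)
                if ci == n_conv - 1 and g_u_extra is not None:
                    gu = gu + g_u_extra
                gu_next[ci] = gu
                g_drive = gu / taus[ci]
                g.conv_biases[ci] += g_drive.sum(axis=(1, 2))
                g.kernels[ci] += conv_kernel_grad(
                    cache.V_below[ci][t], g_drive, g.kernels[ci].shape
                )
                # the gradient w.r.t. the raw input frame is never used, so
                # the bottom layer skips the transposed convolution
                g_v = conv_input_grad(g_drive, params.kernels[ci]) if ci > 0 else None
                ci -= 1

    inv_T = 1.0 / T
    for k in g.kernels:
        k *= inv_T
    for b in g.conv_biases:
        b *= inv_T
    g.head_weight *= inv_T
    g.head_bias *= inv_T
    if not g.all_finite():
        raise TrainingDiverged("non-finite gradient encountered during BPTT")
    return g, ledger, Y


# ---------------------------------------------------------------------------
# updates


def apply_update(
    params: Parameters, grads: GradientSet, lr: float, weight_decay: float = WEIGHT_DECAY
) -> Parameters:
    """One SGD step: k <- k - lr (dE/dk + decay k) for kernel and output
    weights; b <- b - lr dE/db for biases (no decay on biases)."""
    new = Parameters(
        kernels=[
            k - lr * (gk + weight_decay * k) for k, gk in zip(params.kernels, grads.kernels)
        ],
        conv_biases=[
            b - lr * gb for b, gb in zip(params.conv_biases, grads.conv_biases)
        ],
        head_weight=params.head_weight
        - lr * (grads.head_weight + weight_decay * params.head_weight),
        head_bias=params.head_bias - lr * grads.head_bias,
    )
    if not new.all_finite():
        raise TrainingDiverged("non-finite parameter after update")
    return new


def adapt_learning_rate(lr: float, error_prev: float, error_now: float) -> float:
    """Bold-driver schedule: x1.05 on strict epoch-error decrease, /2
    otherwise (ties count as 'otherwise')."""
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    return lr * 1.05 if error_now < error_prev else lr / 2.0


def initialize_parameters(spec: ArchitectureSpec, sigma: float = 0.05, seed: int = 0) -> Parameters:
    """Draw every kernel weight and bias i.i.d. from N(0, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    shapes = parameter_shapes(spec)
    return Parameters(
        kernels=[rng.normal(0.0, sigma, s) for s in shapes["kernels"]],
        conv_biases=[rng.normal(0.0, sigma, s) for s in shapes["conv_biases"]],
        head_weight=rng.normal(0.0, sigma, shapes["head_weight"]),
        head_bias=rng.normal(0.0, sigma, shapes["head_bias"]),
    )


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainingConfig:
    """Hyper-parameters of the SGD loop; defaults are the reference values."""

    learning_rate: float = 0.1
    weight_decay: float = WEIGHT_DECAY
    lr_up: float = 1.05
    lr_down: float = 2.0
    epochs: int = 50
    init_sigma: float = 0.05
    delay: int = 15
    seed: int = 0
    shuffle: bool = True
    monitor: str = "mse"  # "mse" (default) or "kl" for lr adaptation
    window: str = "final"

    def __post_init__(self):
        for name in ("learning_rate", "weight_decay", "lr_up", "lr_down", "init_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0 or self.delay < 1:
            raise ValueError("epochs must be >= 0 and delay >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _vote(Y: np.ndarray, d: int) -> int:
    """Majority vote over the final d steps; ties broken by summed
    probability, then lowest class index."""
    window = Y[-d:]
    votes = window.argmax(axis=1)
    counts = np.bincount(votes, minlength=Y.shape[1])
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    sums = window[:, tied].sum(axis=0)
    return int(tied[np.argmax(sums)])


def train(
    dataset,
    config: TrainingConfig,
    spec: ArchitectureSpec,
    params: Parameters | None = None,
    callback=None,
    stop_fn=None,
):
    """Per-sequence SGD over ``dataset`` (VideoSequences already carrying
    their black frames).

    Returns (params, log) where log is a DataFrame with one row per epoch:
    epoch, mean_error (the monitored quantity), mean_kl, learning_rate,
    train_accuracy.  ``callback(epoch, params)`` runs after each epoch;
    ``stop_fn(row)`` may end training early (e.g. once training accuracy
    saturates) -- ``config.epochs`` is then the cap, not the exact count.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    C = spec.n_classes
    for seq in dataset:
        if not 0 <= seq.label < C:
            raise ValueError(f"label {seq.label} out of range for {C} classes")
    if params is None:
        params = initialize_parameters(spec, config.init_sigma, config.seed)
    rng = np.random.default_rng(config.seed)
    lr = config.learning_rate
    prev_monitor = None
    rows = []
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        for i in order:
            seq = dataset[i]
            try:
                grads, ledger, _ = backprop_through_time(
                    seq.frames, seq.label, params, spec, config.delay, config.window
                )
            except TrainingDiverged as exc:
                raise TrainingDiverged(
                    f"epoch {epoch}, sequence {i} (subject {seq.subject}): {exc}"
                ) from exc
            params = apply_update(params, grads, lr, config.weight_decay)
        # the monitored error is calculated subsequent to the epoch, with
        # the end-of-epoch parameters fixed
        kl_sum = mse_sum = 0.0
        correct = 0
        for seq in dataset:
            Y, _ = forward_sequence(params, spec, seq.frames)
            ystar = one_hot(seq.label, C)
            ledger = sequence_loss(Y, ystar, config.delay, config.window)
            kl_sum += ledger.total
            mse_sum += float(np.mean((Y[ledger.mask] - ystar) ** 2))
            correct += _vote(Y, config.delay) == seq.label
        monitor = mse_sum / n if config.monitor == "mse" else kl_sum / n
        rows.append(
            {
                "epoch": epoch,
                "mean_error": monitor,
                "mean_kl": kl_sum / n,
                "learning_rate": lr,
                "train_accuracy": correct / n,
            }
        )
        if prev_monitor is not None:
            lr = adapt_learning_rate(lr, prev_monitor, monitor)
        prev_monitor = monitor
        if callback is not None:
            callback(epoch, params)
        if stop_fn is not None and stop_fn(rows[-1]):
            break
    return params, pd.DataFrame(rows)
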