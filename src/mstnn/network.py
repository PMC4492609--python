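"""Forward dynamics of the leaky-integrator convolutional network.

Each convolutional unit keeps an internal state u that decays toward its
convolutional drive at rate 1/tau per frame:

    u_t = (1 - 1/tau) * u_{t-1} + (1/tau) * (sum_n k_mn * v_below_n + b_m)
    v_t = 1.7159 * tanh((2/3) * u_t)

where ``*`` is a stride-1, valid cross-correlation (no kernel flip).
Max-pooling takes non-overlapping window maxima (argmax positions are
recorded so gradients can be routed back).  The output head is a static
affine map of the top hidden layer followed by a softmax, recomputed at
every time step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import ArchitectureSpec, validate_architecture

# Activation scaling after LeCun: f(u) = 1.7159 tanh(2u/3), so that
# f(1) ~ 1 and the second derivative peaks near unit variance inputs.
TANH_SCALE = 1.7159
TANH_SLOPE = 2.0 / 3.0


def scaled_tanh(u):
    """Element-wise 1.7159 * tanh((2/3) u)."""
    return TANH_SCALE * np.tanh(TANH_SLOPE * np.asarray(u, dtype=float))


def scaled_tanh_deriv(u):
    """Derivative of :func:`scaled_tanh` with respect to u."""
    th = np.tanh(TANH_SLOPE * np.asarray(u, dtype=float))
    return TANH_SCALE * TANH_SLOPE * (1.0 - th * th)


def softmax(s):
    """Stable softmax over the last axis (invariant to additive shifts)."""
    s = np.asarray(s, dtype=float)
    z = s - s.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class Parameters:
    """Learnable parameters: per-conv-layer kernels (m, n, kr, kc) and
    biases (m,), plus the output head weight (C, F) and bias (C,)."""

    kernels: list
    conv_biases: list
    head_weight: np.ndarray
    head_bias: np.ndarray

    def copy(self) -> "Parameters":
        return Parameters(
            [k.copy() for k in self.kernels],
            [b.copy() for b in self.conv_biases],
            self.head_weight.copy(),
            self.head_bias.copy(),
        )

    def flat(self) -> np.ndarray:
        """All parameters concatenated into one vector (for diagnostics
        and finite-difference checks)."""
        parts = [k.ravel() for k in self.kernels]
        parts += [b.ravel() for b in self.conv_biases]
        parts += [self.head_weight.ravel(), self.head_bias.ravel()]
        return np.concatenate(parts)

    def all_finite(self) -> bool:
        return bool(np.isfinite(self.flat()).all())


def parameter_shapes(spec: ArchitectureSpec) -> dict:
    """Shapes of every parameter array implied by an architecture."""
    kernels, biases = [], []
    prev_maps = spec.input_layer.maps
    for l in spec.hidden:
        if l.role == "convolutional":
            kr, kc = l.kernel
            kernels.append((l.maps, prev_maps, kr, kc))
            biases.append((l.maps,))
        prev_maps = l.maps
    return {
        "kernels": kernels,
        "conv_biases": biases,
        "head_weight": (spec.n_classes, spec.head_input_size),
        "head_bias": (spec.n_classes,),
    }


def zero_parameters(spec: ArchitectureSpec) -> Parameters:
    shapes = parameter_shapes(spec)
    return Parameters(
        [np.zeros(s) for s in shapes["kernels"]],
        [np.zeros(s) for s in shapes["conv_biases"]],
        np.zeros(shapes["head_weight"]),
        np.zeros(shapes["head_bias"]),
    )


def check_shapes(params: Parameters, spec: ArchitectureSpec) -> None:
    shapes = parameter_shapes(spec)
    for i, (k, s) in enumerate(zip(params.kernels, shapes["kernels"])):
        if k.shape != s:
            raise ValueError(f"kernel {i} has shape {k.shape}, expected {s}")
    if len(params.kernels) != len(shapes["kernels"]):
        raise ValueError("wrong number of convolutional layers in parameters")
    if params.head_weight.shape != shapes["head_weight"]:
        raise ValueError(
            f"head weight shape {params.head_weight.shape}, "
            f"expected {shapes['head_weight']}"
        )


def save_checkpoint(path, params: Parameters, spec: ArchitectureSpec) -> None:
    """Persist parameters plus the architecture (and its hash) in one file."""
    arrays = {f"kernel_{i}": k for i, k in enumerate(params.kernels)}
    arrays.update({f"bias_{i}": b for i, b in enumerate(params.conv_biases)})
    arrays["head_weight"] = params.head_weight
    arrays["head_bias"] = params.head_bias
    arrays["spec_json"] = np.array(json.dumps(spec.to_dict()))
    arrays["spec_hash"] = np.array(spec.hash())
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load (params, spec) saved by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as z:
        spec = validate_architecture(
            ArchitectureSpec.from_dict(json.loads(str(z["spec_json"])))
        )
        n_conv = len(spec.conv_indices)
        params = Parameters(
            [z[f"kernel_{i}"] for i in range(n_conv)],
            [z[f"bias_{i}"] for i in range(n_conv)],
            z["head_weight"],
            z["head_bias"],
        )
    check_shapes(params, spec)
    return params, spec


# ---------------------------------------------------------------------------
# primitive layer operations


def conv_drive(v_below: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid stride-1 cross-correlation summed over input maps, plus bias.

    v_below: (n, R, C); kernels: (m, n, kr, kc); returns (m, R-kr+1, C-kc+1).
    """
    m, n, kr, kc = kernels.shape
    if v_below.shape[0] != n:
        raise ValueError(
            f"input has {v_below.shape[0]} maps, kernel expects {n}"
        )
    if v_below.shape[1] < kr or v_below.shape[2] < kc:
        raise ValueError("kernel larger than input map")
    win = sliding_window_view(v_below, (kr, kc), axis=(1, 2))  # (n,oR,oC,kr,kc)
    out = np.tensordot(kernels, win, axes=([1, 2, 3], [0, 3, 4]))
    return out + bias[:, None, None]


def conv_kernel_grad(v_below: np.ndarray, g_drive: np.ndarray, kernel_shape) -> np.ndarray:
    """Gradient of the drive w.r.t. the shared kernel: correlation of the
    input with the drive gradient, summed over all spatial placements."""
    m, n, kr, kc = kernel_shape
    oR, oC = g_drive.shape[1:]
    win = sliding_window_view(v_below, (oR, oC), axis=(1, 2))  # (n,kr,kc,oR,oC)
    return np.tensordot(g_drive, win, axes=([1, 2], [3, 4]))  # (m,n,kr,kc)


def conv_input_grad(g_drive: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Gradient of the drive w.r.t. the layer input (transposed
    convolution): one kernel-transpose GEMM followed by a scatter-add of
    each kernel offset's contribution onto the input grid."""
    m, n, kr, kc = kernels.shape
    oR, oC = g_drive.shape[1:]
    R, C = oR + kr - 1, oC + kc - 1
    # contrib[n, i, j, r, c] = sum_m kernels[m, n, i, j] * g_drive[m, r, c]
    contrib = np.tensordot(kernels, g_drive, axes=([0], [0]))
    out = np.zeros((n, R, C))
    for i in range(kr):
        for j in range(kc):
            out[:, i : i + oR, j : j + oC] += contrib[:, i, j]
    return out


def max_pool(v: np.ndarray, pool: int):
    """Non-overlapping window maximum per map.

    Returns (pooled, argmax) where argmax holds the flat within-window
    index of each maximum (first occurrence on ties) for gradient routing.
    """
    m, R, C = v.shape
    if R % pool or C % pool:
        raise ValueError(f"pool size {pool} does not divide map {R}x{C}")
    pR, pC = R // pool, C // pool
    blocks = (
        v.reshape(m, pR, pool, pC, pool).transpose(0, 1, 3, 2, 4).reshape(m, pR, pC, -1)
    )
    idx = blocks.argmax(axis=-1)
    pooled = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def max_unpool(g: np.ndarray, idx: np.ndarray, pool: int, shape) -> np.ndarray:
    """Route pooled gradients back to the recorded argmax positions."""
    m, R, C = shape
    pR, pC = R // pool, C // pool
    out = np.zeros((m, pR, pC, pool * pool), dtype=float)
    np.put_along_axis(out, idx[..., None], g[..., None], axis=-1)
    return (
        out.reshape(m, pR, pC, pool, pool).transpose(0, 1, 3, 2, 4).reshape(m, R, C)
    )


def output_internal_states(v_top, head_weight, head_bias):
    """Static affine output head: s = W . flatten(v_top) + b."""
    flat = np.asarray(v_top, dtype=float).ravel()
    if flat.size != head_weight.shape[1]:
        raise ValueError(
            f"head expects {head_weight.shape[1]} inputs, got {flat.size}"
        )
    return head_weight @ flat + head_bias


# ---------------------------------------------------------------------------
# network state and single-step dynamics


@dataclass
class NetworkState:
    """Internal states u and activations v of every convolutional layer,
    output internal states s, and the step index t."""

    u: list
    v: list
    s: np.ndarray
    t: int = 0


def reset_state(spec: ArchitectureSpec) -> NetworkState:
    """Fresh state with all internal states at exactly zero (t = 0)."""
    u = []
    for i in spec.conv_indices:
        l = spec.layers[i]
        u.append(np.zeros((l.maps, l.rows, l.cols)))
    v = [np.zeros_like(a) for a in u]
    return NetworkState(u=u, v=v, s=np.zeros(spec.n_classes), t=0)


def leaky_integrate_conv(u_prev, v_below, kernels, bias, tau):
    """One leaky-integrator update of a convolutional layer.

    Returns (u, v): the new internal state and its activation.  With
    tau = 1 the state equals the drive exactly (memoryless).
    """
    if tau < 1:
        raise ValueError(f"time constant must be >= 1, got {tau}")
    drive = conv_drive(v_below, kernels, bias)
    if drive.shape != u_prev.shape:
        raise ValueError(
            f"drive shape {drive.shape} does not match state {u_prev.shape}"
        )
    u = (1.0 - 1.0 / tau) * u_prev + drive / tau
    return u, scaled_tanh(u)


def forward_step(state: NetworkState, params: Parameters, spec: ArchitectureSpec, frame):
    """One bottom-up sweep: frame -> conv/pool stack -> head -> softmax.

    Layer l at step t reads the same-step activations of layer l-1.
    Returns (new_state, y) with y the class distribution at this step.
    """
    frame = np.asarray(frame, dtype=float)
    il = spec.input_layer
    if frame.shape != (il.rows, il.cols):
        raise ValueError(
            f"frame shape {frame.shape} does not match input layer "
            f"({il.rows}, {il.cols})"
        )
    below = frame[None]  # input layer exposes one map
    new_u, new_v = [], []
    ci = 0
    for l in spec.hidden:
        if l.role == "convolutional":
            u, v = leaky_integrate_conv(
                state.u[ci], below, params.kernels[ci], params.conv_biases[ci], l.tau
            )
            new_u.append(u)
            new_v.append(v)
            below = v
            ci += 1
        else:  # max_pooling
            below, _ = max_pool(below, l.pool)
    head_in = new_u[-1] if spec.head_reads == "internal" else below
    s = output_internal_states(head_in, params.head_weight, params.head_bias)
    y = softmax(s)
    return NetworkState(u=new_u, v=new_v, s=s, t=state.t + 1), y


# ---------------------------------------------------------------------------
# whole-sequence forward pass with cache (used by training and analysis)


@dataclass
class ForwardCache:
    """Everything the backward pass and the analysis tools need from one
    forward sweep over a sequence of T frames."""

    U: list  # per conv layer: (T, m, r, c) internal states
    V_below: list  # per conv layer: (T, n, R, C) inputs it correlated with
    pool_idx: list  # per pool layer: (T, m, pR, pC) argmax indices
    head_in: np.ndarray  # (T, F) flattened head inputs
    S: np.ndarray  # (T, C) output internal states
    Y: np.ndarray  # (T, C) class distributions

    def conv_activations(self, conv_layer_pos: int) -> np.ndarray:
        """Activations v of the conv layer at position ``conv_layer_pos``
        (0 = first conv layer), shaped (T, units)."""
        u = self.U[conv_layer_pos]
        return scaled_tanh(u).reshape(u.shape[0], -1)


def forward_sequence(params: Parameters, spec: ArchitectureSpec, frames, cache: bool = False):
    """Run the network over a whole sequence from a reset state.

    Returns (Y, cache) where Y is (T, C); cache is a :class:`ForwardCache`
    when requested, else None.
    """
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    conv_layers = [spec.layers[i] for i in spec.conv_indices]
    pool_layers = [l for l in spec.hidden if l.role == "max_pooling"]
    u_prev = [np.zeros((l.maps, l.rows, l.cols)) for l in conv_layers]

    U = [np.empty((T,) + a.shape) for a in u_prev] if cache else None
    Vb = None
    Pidx = None
    head_in_hist = np.empty((T, spec.head_input_size))
    S = np.empty((T, spec.n_classes))
    if cache:
        Vb = []
        prev_maps, prev_r, prev_c = 1, spec.input_layer.rows, spec.input_layer.cols
        for l in spec.hidden:
            if l.role == "convolutional":
                Vb.append(np.empty((T, prev_maps, prev_r, prev_c)))
            prev_maps, prev_r, prev_c = l.maps, l.rows, l.cols
        Pidx = [np.empty((T, l.maps, l.rows, l.cols), dtype=np.int64) for l in pool_layers]

    for t in range(T):
        below = frames[t][None]
        ci = pi = 0
        u_top = None
        for l in spec.hidden:
            if l.role == "convolutional":
                if cache:
                    Vb[ci][t] = below
                u, v = leaky_integrate_conv(
                    u_prev[ci], below, params.kernels[ci], params.conv_biases[ci], l.tau
                )
                u_prev[ci] = u
                if cache:
                    U[ci][t] = u
                below = v
                u_top = u
                ci += 1
            else:
                below, idx = max_pool(below, l.pool)
                if cache:
                    Pidx[pi][t] = idx
                pi += 1
        head_in = u_top if spec.head_reads == "internal" else below
        head_in_hist[t] = head_in.ravel()
        S[t] = params.head_weight @ head_in_hist[t] + params.head_bias
    Y = softmax(S)
    if cache:
        return Y, ForwardCache(U=U, V_below=Vb, pool_idx=Pidx, head_in=head_in_hist, S=S, Y=Y)
    return Y, None
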