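"""Independent reference implementations used only to cross-check the
package: a naive per-frame static convolutional network (forward and
backward, plain Python loops), written without reference to the package's
vectorized code paths."""

import numpy as np


def naive_correlate(v, k):
    """Valid stride-1 cross-correlation of one map stack with one kernel
    stack, via explicit loops."""
    n, R, C = v.shape
    m, n2, kr, kc = k.shape
    assert n == n2
    out = np.zeros((m, R - kr + 1, C - kc + 1))
    for mi in range(m):
        for r in range(R - kr + 1):
            for c in range(C - kc + 1):
                acc = 0.0
                for ni in range(n):
                    acc += float(np.sum(v[ni, r : r + kr, c : c + kc] * k[mi, ni]))
                out[mi, r, c] = acc
    return out


def naive_pool(v, p):
    m, R, C = v.shape
    out = np.zeros((m, R // p, C // p))
    for mi in range(m):
        for r in range(R // p):
            for c in range(C // p):
                out[mi, r, c] = v[mi, r * p : (r + 1) * p, c * p : (c + 1) * p].max()
    return out


def static_forward(frame, layers, head_w, head_b):
    """Per-frame static network: each conv layer applies kernel + bias and
    the 1.7159 tanh(2u/3) activation with no temporal state.

    ``layers`` is a list of ("conv", k, b) / ("pool", p) tuples.
    Returns (s, y, top, inter): output internal states, class
    distribution, flattened head input, and per-layer intermediates.
    """
    below = frame[None].astype(float)
    inter = []
    for kind, *args in layers:
        if kind == "conv":
            k, b = args
            u = naive_correlate(below, k) + b[:, None, None]
            v = 1.7159 * np.tanh((2.0 / 3.0) * u)
            inter.append(("conv", below.copy(), u))
            below = v
        else:
            (p,) = args
            inter.append(("pool", below.copy(), p))
            below = naive_pool(below, p)
    s = head_w @ below.ravel() + head_b
    e = np.exp(s - s.max())
    y = e / e.sum()
    return s, y, below, inter


def static_backward(frame, label, layers, head_w, head_b):
    """Exact gradient of -ln y[label] for the static per-frame network by
    explicit chain rule with loops.

    Returns (gW, gb_head, conv_grads) where conv_grads is a list of
    (gk, gbias) per conv layer, bottom first.
    """
    s, y, top, inter = static_forward(frame, layers, head_w, head_b)
    ds = y.copy()
    ds[label] -= 1.0
    gW = np.outer(ds, top.ravel())
    gb_head = ds.copy()
    g = (head_w.T @ ds).reshape(top.shape)

    conv_grads = []
    for (kind, *args), item in zip(reversed(layers), reversed(inter)):
        if kind == "conv":
            k, _b = args
            _, below, u = item
            th = np.tanh((2.0 / 3.0) * u)
            gu = g * 1.7159 * (2.0 / 3.0) * (1.0 - th * th)
            m, n, kr, kc = k.shape
            oR, oC = gu.shape[1:]
            gk = np.zeros_like(k)
            gbelow = np.zeros_like(below)
            for mi in range(m):
                for r in range(oR):
                    for c in range(oC):
                        for ni in range(n):
                            gk[mi, ni] += gu[mi, r, c] * below[ni, r : r + kr, c : c + kc]
                            gbelow[ni, r : r + kr, c : c + kc] += gu[mi, r, c] * k[mi, ni]
            conv_grads.append((gk, gu.sum(axis=(1, 2))))
            g = gbelow
        else:
            (p,) = args
            _, below, _p = item
            m, R, C = below.shape
            gbelow = np.zeros_like(below)
            for mi in range(m):
                for r in range(R // p):
                    for c in range(C // p):
                        block = below[mi, r * p : (r + 1) * p, c * p : (c + 1) * p]
                        rr, cc = np.unravel_index(block.argmax(), block.shape)
                        gbelow[mi, r * p + rr, c * p + cc] = g[mi, r, c]
            g = gbelow
    conv_grads.reverse()
    return gW, gb_head, conv_grads
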