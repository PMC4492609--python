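"""Declarative network architecture: layer stack, validation, serialization.

The model is a stack of retinotopic layers: an input layer, alternating
convolutional and max-pooling layers, and a fully-connected softmax output
head.  Convolutional layers are populated by leaky-integrator units whose
time constant ``tau`` sets the layer's dynamical timescale; ``tau`` is
required to be non-decreasing with depth so that higher layers integrate
over longer temporal windows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import yaml

ROLES = ("input", "convolutional", "max_pooling", "fully_connected")


class ArchitectureError(ValueError):
    """Raised when a layer stack is internally inconsistent."""


@dataclass(frozen=True)
class Layer:
    """One layer record.

    ``rows``/``cols`` are the spatial feature-map dimensions (row-major:
    a "48x54" frame is 48 rows by 54 columns).  ``kernel`` is
    (kernel_rows, kernel_cols) for convolutional layers, ``pool`` the
    square window size for max-pooling layers, ``tau`` the leaky
    integrator time constant (>= 1), and ``classes`` the output
    dimension of the fully-connected head.
    """

    role: str
    maps: int = 1
    rows: int = 1
    cols: int = 1
    kernel: tuple[int, int] | None = None
    pool: int | None = None
    tau: float | None = None
    classes: int | None = None


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer stack plus the output-head wiring convention.

    ``head_reads`` selects whether the fully-connected head consumes the
    post-activation values ``v`` ("activation", default) or the raw
    internal states ``u`` ("internal") of the top hidden layer.
    """

    layers: tuple[Layer, ...]
    head_reads: str = "activation"

    # -- convenience views -------------------------------------------------
    @property
    def input_layer(self) -> Layer:
        return self.layers[0]

    @property
    def hidden(self) -> tuple[Layer, ...]:
        """All layers between input and the fully-connected head."""
        return self.layers[1:-1]

    @property
    def conv_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, l in enumerate(self.layers) if l.role == "convolutional"
        )

    @property
    def n_classes(self) -> int:
        return int(self.layers[-1].classes)

    @property
    def head_input_size(self) -> int:
        top = self.layers[-2]
        return top.maps * top.rows * top.cols

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(self.layers[i].tau for i in self.conv_indices)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        layers = []
        for l in self.layers:
            rec = {"role": l.role, "maps": l.maps, "rows": l.rows, "cols": l.cols}
            if l.kernel is not None:
                rec["kernel"] = list(l.kernel)
            if l.pool is not None:
                rec["pool"] = l.pool
            if l.tau is not None:
                rec["tau"] = float(l.tau)
            if l.classes is not None:
                rec["classes"] = l.classes
            layers.append(rec)
        return {"head_reads": self.head_reads, "layers": layers}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        layers = []
        for rec in d["layers"]:
            kernel = tuple(rec["kernel"]) if "kernel" in rec else None
            layers.append(
                Layer(
                    role=rec["role"],
                    maps=int(rec.get("maps", 1)),
                    rows=int(rec.get("rows", 1)),
                    cols=int(rec.get("cols", 1)),
                    kernel=kernel,
                    pool=rec.get("pool"),
                    tau=rec.get("tau"),
                    classes=rec.get("classes"),
                )
            )
        return cls(layers=tuple(layers), head_reads=d.get("head_reads", "activation"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ArchitectureSpec":
        with open(path) as fh:
            return validate_architecture(cls.from_dict(yaml.safe_load(fh)))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_architecture(spec: ArchitectureSpec) -> ArchitectureSpec:
    """Check a layer stack for internal consistency and return it.

    Verifies the valid-convolution dimension chain (stride 1, no
    padding), exact pool divisibility, ``tau >= 1`` non-decreasing with
    depth, and the input/fully-connected bracketing of the stack.
    """
    layers = spec.layers
    if len(layers) < 2:
        raise ArchitectureError("architecture needs at least input and output layers")
    if layers[0].role != "input":
        raise ArchitectureError("layer 0 must have role 'input'")
    if layers[-1].role != "fully_connected":
        raise ArchitectureError("last layer must have role 'fully_connected'")
    if spec.head_reads not in ("activation", "internal"):
        raise ArchitectureError(f"unknown head_reads {spec.head_reads!r}")
    if spec.head_reads == "internal" and layers[-2].role != "convolutional":
        raise ArchitectureError("head_reads='internal' requires a convolutional top hidden layer")

    prev_tau = None
    for i, l in enumerate(layers):
        if l.role not in ROLES:
            raise ArchitectureError(f"layer {i}: unknown role {l.role!r}")
        if i == 0:
            if l.maps < 1 or l.rows < 1 or l.cols < 1:
                raise ArchitectureError(f"layer {i}: non-positive input dimensions")
            continue
        prev = layers[i - 1]
        if l.role == "convolutional":
            if l.kernel is None:
                raise ArchitectureError(f"layer {i}: convolutional layer needs a kernel size")
            kr, kc = l.kernel
            if kr < 1 or kc < 1:
                raise ArchitectureError(f"layer {i}: non-positive kernel")
            er, ec = prev.rows - kr + 1, prev.cols - kc + 1
            if (l.rows, l.cols) != (er, ec):
                raise ArchitectureError(
                    f"layer {i}: declared {l.rows}x{l.cols} but valid convolution of "
                    f"{prev.rows}x{prev.cols} with kernel {kr}x{kc} gives {er}x{ec}"
                )
            if er < 1 or ec < 1:
                raise ArchitectureError(f"layer {i}: kernel larger than input map")
            if l.tau is None or l.tau < 1:
                raise ArchitectureError(
                    f"layer {i}: time constant must be >= 1 (got {l.tau})"
                )
            if prev_tau is not None and l.tau < prev_tau:
                raise ArchitectureError(
                    f"layer {i}: time constant {l.tau} decreases with depth "
                    f"(previous convolutional layer has tau={prev_tau})"
                )
            prev_tau = l.tau
        elif l.role == "max_pooling":
            if l.pool is None or l.pool < 1:
                raise ArchitectureError(f"layer {i}: pooling layer needs a positive pool size")
            if prev.rows % l.pool or prev.cols % l.pool:
                raise ArchitectureError(
                    f"layer {i}: pool size {l.pool} does not divide "
                    f"{prev.rows}x{prev.cols}"
                )
            if l.maps != prev.maps:
                raise ArchitectureError(
                    f"layer {i}: pooling must preserve map count ({prev.maps})"
                )
            if (l.rows, l.cols) != (prev.rows // l.pool, prev.cols // l.pool):
                raise ArchitectureError(
                    f"layer {i}: declared {l.rows}x{l.cols} but pooling "
                    f"{prev.rows}x{prev.cols} by {l.pool} gives "
                    f"{prev.rows // l.pool}x{prev.cols // l.pool}"
                )
        elif l.role == "fully_connected":
            if i != len(layers) - 1:
                raise ArchitectureError(f"layer {i}: fully_connected must be last")
            if l.classes is None or l.classes < 2:
                raise ArchitectureError(f"layer {i}: needs classes >= 2")
        elif l.role == "input":
            raise ArchitectureError(f"layer {i}: input role only allowed at position 0")
    return spec


def weizmann_architecture(n_classes: int = 10) -> ArchitectureSpec:
    """The 7-layer reference stack for 48x54 silhouette frames.

    1x48x54 input -> conv 6x40x40 (kernel 9x15, tau=2) -> pool 2 ->
    conv 50x14x14 (kernel 7x7, tau=5) -> pool 2 -> conv 100x1x1
    (kernel 7x7, tau=100) -> fully connected softmax head.
    """
    return validate_architecture(
        ArchitectureSpec(
            layers=(
                Layer("input", 1, 48, 54),
                Layer("convolutional", 6, 40, 40, kernel=(9, 15), tau=2.0),
                Layer("max_pooling", 6, 20, 20, pool=2),
                Layer("convolutional", 50, 14, 14, kernel=(7, 7), tau=5.0),
                Layer("max_pooling", 50, 7, 7, pool=2),
                Layer("convolutional", 100, 1, 1, kernel=(7, 7), tau=100.0),
                Layer("fully_connected", classes=n_classes),
            )
        )
    )


def compact_architecture(
    n_classes: int, maps: tuple[int, int, int] = (4, 8, 24)
) -> ArchitectureSpec:
    """Reduced-width variant of the reference stack (same geometry and
    time constants, fewer feature maps) for desk-scale experiments."""
    m1, m2, m3 = maps
    return validate_architecture(
        ArchitectureSpec(
            layers=(
                Layer("input", 1, 48, 54),
                Layer("convolutional", m1, 40, 40, kernel=(9, 15), tau=2.0),
                Layer("max_pooling", m1, 20, 20, pool=2),
                Layer("convolutional", m2, 14, 14, kernel=(7, 7), tau=5.0),
                Layer("max_pooling", m2, 7, 7, pool=2),
                Layer("convolutional", m3, 1, 1, kernel=(7, 7), tau=100.0),
                Layer("fully_connected", classes=n_classes),
            )
        )
    )


def with_top_tau(spec: ArchitectureSpec, tau: float) -> ArchitectureSpec:
    """Return a copy of ``spec`` with the top convolutional layer's time
    constant replaced (lower-layer time constants unchanged)."""
    top = spec.conv_indices[-1]
    layers = list(spec.layers)
    layers[top] = replace(layers[top], tau=float(tau))
    return validate_architecture(
        ArchitectureSpec(layers=tuple(layers), head_reads=spec.head_reads)
    )


def with_all_tau(spec: ArchitectureSpec, tau: float) -> ArchitectureSpec:
    """Return a copy with every convolutional time constant set to ``tau``.

    ``tau=1`` yields the memoryless ablation: each step's output depends
    only on the current frame, i.e. a static per-frame network.
    """
    layers = [
        replace(l, tau=float(tau)) if l.role == "convolutional" else l
        for l in spec.layers
    ]
    return validate_architecture(
        ArchitectureSpec(layers=tuple(layers), head_reads=spec.head_reads)
    )
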