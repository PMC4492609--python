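"""Sequence I/O, preprocessing, occlusion, concatenation, splitting, and
the synthetic silhouette-video generator.

Sequences are short, low-resolution, binarized silhouette-like videos
(48 rows x 54 columns by default), foreground = 1 on background = 0.
The synthetic generator renders a parametric humanoid performing periodic
movements (vertical bounce, one-arm wave, two-arm wave) or a monotone
posture change (crouch-to-stand and its exact time reversal), with
per-subject jitter in phase, body scale, position, and pixel noise so
that "subjects" differ the way real actors do.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

ARCHETYPES = (
    "bounce",
    "one_arm_wave",
    "two_arm_wave",
    "grow",
    "shrink",
    "walk",
    "walk_back",
)


@dataclass
class VideoSequence:
    """Ordered grayscale frames (T, rows, cols) in [0, 1] with a class
    label, a subject identifier, and a provenance tag."""

    frames: np.ndarray
    label: int
    subject: str
    provenance: str = "synthetic"
    name: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, rows, cols) array")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def T(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# frame I/O


def write_sequence(seq: VideoSequence, directory) -> None:
    """Write one frame per PNG file (frame_0000.png, ...)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(seq.T):
        frame = np.clip(np.round(seq.frames[t] * 255), 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"frame_{t:04d}.png", frame)


def read_sequence(directory, label: int, subject: str, provenance: str = "real") -> VideoSequence:
    """Read a directory of lexically ordered PNG/PGM frames into a
    sequence, scaling 8-bit intensities to [0, 1]."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".pgm")
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/PGM frames in {directory}")
    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:  # collapse any color channels to luminance
            img = img.mean(axis=2)
        frames.append(img / 255.0)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame dimensions in {directory}: {shapes}")
    return VideoSequence(np.stack(frames), label, subject, provenance, name=directory.name)


def write_manifest(dataset, root, manifest_name: str = "manifest.csv"):
    """Write every sequence under ``root`` plus a CSV manifest with
    columns sequence_path, label, subject, provenance."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seq in enumerate(dataset):
        name = seq.name or f"seq_{i:04d}"
        write_sequence(seq, root / name)
        rows.append(
            {
                "sequence_path": name,
                "label": seq.label,
                "subject": seq.subject,
                "provenance": seq.provenance,
            }
        )
    path = root / manifest_name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_dataset(manifest_path) -> list:
    """Load every sequence listed in a manifest CSV (paths relative to
    the manifest's directory)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"sequence_path", "label", "subject"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    root = manifest_path.parent
    dataset = []
    for rec in table.itertuples():
        dataset.append(
            read_sequence(
                root / rec.sequence_path,
                int(rec.label),
                str(rec.subject),
                getattr(rec, "provenance", "real"),
            )
        )
    return dataset


# ---------------------------------------------------------------------------
# preprocessing


def normalize_frames(seq: VideoSequence, target_rows: int = 48, target_cols: int = 54) -> VideoSequence:
    """Bilinear-resize every frame to target dims, clipping to [0, 1]."""
    if target_rows < 2 or target_cols < 2:
        raise ValueError("degenerate target dimensions")
    if seq.shape == (target_rows, target_cols):
        return replace(seq, frames=seq.frames.copy())
    down = target_rows < seq.shape[0] or target_cols < seq.shape[1]
    out = np.stack(
        [
            resize(f, (target_rows, target_cols), order=1, anti_aliasing=down,
                   preserve_range=True)
            for f in seq.frames
        ]
    )
    return replace(seq, frames=np.clip(out, 0.0, 1.0))


def append_black_frames(seq: VideoSequence, d: int) -> VideoSequence:
    """Append d all-zero frames (the delay-response label segment)."""
    if d < 1:
        raise ValueError("delay-response training requires d >= 1 black frames")
    black = np.zeros((d,) + seq.shape)
    return replace(seq, frames=np.concatenate([seq.frames, black]))


# ---------------------------------------------------------------------------
# occlusion


@dataclass(frozen=True)
class OcclusionSpec:
    """Moving vertical-stripe occluder.

    ``gap`` is the clear interval between adjacent bars, so the pattern
    period is ``bar_width + gap``.  Bars move ``speed`` pixels per frame
    from right to left (toward lower column indices), wrapping modularly;
    at frame 0 a bar sits flush with the right image edge.
    """

    bar_width: int
    gap: int = 5
    speed: int = 2
    phase: int = 0

    def __post_init__(self):
        if self.bar_width < 0 or self.phase < 0 or self.speed < 0:
            raise ValueError("occlusion parameters must be non-negative")
        if self.bar_width > 0 and self.gap < 1:
            raise ValueError("gap must be >= 1")


def occlusion_mask(n_cols: int, t: int, occ: OcclusionSpec) -> np.ndarray:
    """Boolean mask of occluded columns at frame t."""
    if occ.bar_width == 0:
        return np.zeros(n_cols, dtype=bool)
    period = occ.bar_width + occ.gap
    base = (occ.bar_width - n_cols) % period  # right edge of a bar at col n_cols-1, t=0
    c = np.arange(n_cols)
    return (c + occ.speed * t + base + occ.phase) % period < occ.bar_width


def apply_occlusion(seq: VideoSequence, occ: OcclusionSpec) -> VideoSequence:
    """Zero out the columns covered by the moving stripes in every frame.

    Black frames, if already appended, are unaffected in effect (they are
    zero everywhere).
    """
    if occ.bar_width == 0:
        return replace(seq, frames=seq.frames.copy())
    frames = seq.frames.copy()
    n_cols = seq.shape[1]
    for t in range(seq.T):
        frames[t][:, occlusion_mask(n_cols, t, occ)] = 0.0
    return replace(seq, frames=frames, provenance="occluded")


# ---------------------------------------------------------------------------
# concatenation


@dataclass(frozen=True)
class ConcatenationSpec:
    """Two prototypical actions back to back, then d black frames.

    The composite label is the ordered pair index
    ``first * n_base_actions + second`` (3 base actions -> 9 categories);
    total length is ``2 * frames_per_action + delay``.
    """

    frames_per_action: int = 42
    delay: int = 15
    n_base_actions: int = 3


def concatenate_actions(seq_a: VideoSequence, seq_b: VideoSequence, spec: ConcatenationSpec) -> VideoSequence:
    f = spec.frames_per_action
    if seq_a.T < f or seq_b.T < f:
        raise ValueError(f"source sequences must have at least {f} frames")
    if seq_a.subject != seq_b.subject:
        raise ValueError(
            f"subject mismatch: {seq_a.subject!r} vs {seq_b.subject!r}"
        )
    if seq_a.shape != seq_b.shape:
        raise ValueError("frame dimension mismatch between sources")
    frames = np.concatenate(
        [seq_a.frames[:f], seq_b.frames[:f], np.zeros((spec.delay,) + seq_a.shape)]
    )
    label = seq_a.label * spec.n_base_actions + seq_b.label
    return VideoSequence(
        frames,
        label,
        seq_a.subject,
        provenance="concatenated",
        name=f"{seq_a.subject}_pair_{seq_a.label}{seq_b.label}",
    )


# ---------------------------------------------------------------------------
# synthetic silhouette generator


@dataclass(frozen=True)
class SyntheticActionSpec:
    """One rendered silhouette video of a parametric humanoid mover.

    ``archetype`` selects the spatio-temporal pattern; archetypes differ
    in structure over time, not in marginal pixel statistics, so some
    class pairs require temporal processing to separate.  Jitter fields
    (phase, scale, offsets, noise) encode the "subject".
    """

    archetype: str
    length: int = 40
    rows: int = 48
    cols: int = 54
    period: float = 16.0
    amplitude: float = 5.0
    body_scale: float = 1.0
    phase: float = 0.0
    col_offset: int = 0
    row_offset: int = 0
    noise_rate: float = 0.01
    seed: int = 0


def _paint_box(canvas, grid_r, grid_c, r0, r1, c0, c1):
    canvas |= (grid_r >= r0) & (grid_r <= r1) & (grid_c >= c0) & (grid_c <= c1)


def _paint_disc(canvas, grid_r, grid_c, cr, cc, radius):
    canvas |= (grid_r - cr) ** 2 + (grid_c - cc) ** 2 <= radius**2


def _paint_segment(canvas, grid_r, grid_c, p0, p1, half_width):
    (r0, c0), (r1, c1) = p0, p1
    dr, dc = r1 - r0, c1 - c0
    L2 = dr * dr + dc * dc
    if L2 == 0:
        _paint_disc(canvas, grid_r, grid_c, r0, c0, half_width)
        return
    tproj = np.clip(((grid_r - r0) * dr + (grid_c - c0) * dc) / L2, 0.0, 1.0)
    dist2 = (grid_r - (r0 + tproj * dr)) ** 2 + (grid_c - (c0 + tproj * dc)) ** 2
    canvas |= dist2 <= half_width**2


def _render_figure(rows, cols, feet_row, center_col, scale, arm_angles, height_scale):
    """Paint one humanoid silhouette; arm angles are measured from the
    downward vertical, positive swinging outward and up (pi = overhead)."""
    grid_r, grid_c = np.mgrid[0:rows, 0:cols].astype(float)
    canvas = np.zeros((rows, cols), dtype=bool)
    h = 34.0 * scale * 1.0  # nominal full body height in pixels
    leg_h = 0.35 * h * height_scale
    torso_h = 0.40 * h * height_scale
    head_r = 0.12 * h
    torso_w = 0.22 * h
    hip_row = feet_row - leg_h
    shoulder_row = hip_row - torso_h
    # legs
    _paint_box(canvas, grid_r, grid_c, hip_row, feet_row,
               center_col - 0.45 * torso_w, center_col - 0.05 * torso_w)
    _paint_box(canvas, grid_r, grid_c, hip_row, feet_row,
               center_col + 0.05 * torso_w, center_col + 0.45 * torso_w)
    # torso
    _paint_box(canvas, grid_r, grid_c, shoulder_row, hip_row,
               center_col - torso_w / 2, center_col + torso_w / 2)
    # head
    _paint_disc(canvas, grid_r, grid_c, shoulder_row - head_r - 1.0, center_col, head_r)
    # arms
    arm_len = 0.38 * h
    arm_w = 0.045 * h + 0.8
    for side, angle in zip((-1.0, 1.0), arm_angles):
        if angle is None:
            continue
        p0 = (shoulder_row + 1.0, center_col + side * torso_w / 2)
        p1 = (
            p0[0] + arm_len * np.cos(angle),
            p0[1] + side * arm_len * np.sin(angle),
        )
        _paint_segment(canvas, grid_r, grid_c, p0, p1, arm_w)
    return canvas


def generate_synthetic_action(spec: SyntheticActionSpec) -> VideoSequence:
    """Render one silhouette video; seeded and bit-reproducible.

    ``shrink`` is rendered as the exact frame reversal of ``grow`` with
    identical parameters, so the two classes share per-frame pixel
    histograms and differ only in temporal order.
    """
    if spec.archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {spec.archetype!r}; choose from {ARCHETYPES}")
    reversed_of = {"shrink": "grow", "walk_back": "walk"}
    base = reversed_of.get(spec.archetype, spec.archetype)
    rng = np.random.default_rng(spec.seed)
    T = spec.length
    frames = np.zeros((T, spec.rows, spec.cols))
    center_col = spec.cols / 2.0 + spec.col_offset
    base_feet = spec.rows - 5.0 + spec.row_offset
    hang = np.deg2rad(12.0)
    for t in range(T):
        osc = np.sin(2.0 * np.pi * t / spec.period + spec.phase)
        feet_row = base_feet
        height_scale = 1.0
        arms = (hang, hang)
        col = center_col
        if base == "bounce":
            feet_row = base_feet - spec.amplitude * 0.5 * (1.0 + osc)
        elif base == "one_arm_wave":
            arms = (hang, np.deg2rad(105.0 + 60.0 * osc))
        elif base == "two_arm_wave":
            a = np.deg2rad(105.0 + 60.0 * osc)
            arms = (a, a)
        elif base == "grow":
            height_scale = 0.55 + 0.45 * t / max(T - 1, 1)
        elif base == "walk":
            # translate across the frame at a natural gait (~0.8 px/frame
            # at this resolution) with a slight vertical bob
            span = 0.60 * spec.cols
            col = center_col - span / 2.0 + span * t / max(T - 1, 1)
            feet_row = base_feet - 1.5 * (1.0 + osc) / 2.0
        frames[t] = _render_figure(
            spec.rows, spec.cols, feet_row, col, spec.body_scale, arms, height_scale
        ).astype(float)
    # salt-and-pepper pixel noise, applied before any time reversal
    if spec.noise_rate > 0:
        salt = rng.random(frames.shape) < spec.noise_rate / 2.0
        pepper = rng.random(frames.shape) < spec.noise_rate / 2.0
        frames[salt] = 1.0
        frames[pepper] = 0.0
    if spec.archetype in reversed_of:
        frames = frames[::-1].copy()
    return VideoSequence(frames, label=0, subject="", provenance="synthetic")


def _subject_jitter(seed: int, subject_idx: int, trial: int):
    rng = np.random.default_rng(np.random.SeedSequence([seed, subject_idx, trial]))
    return {
        "phase": float(rng.uniform(0.0, 2.0 * np.pi)),
        "body_scale": float(rng.uniform(0.88, 1.12)),
        "col_offset": int(rng.integers(-3, 4)),
        "row_offset": int(rng.integers(-2, 3)),
        "seed": int(rng.integers(0, 2**31 - 1)),
    }


def make_action_dataset(
    archetypes=("bounce", "one_arm_wave", "two_arm_wave"),
    n_subjects: int = 9,
    n_trials: int = 1,
    length: int = 40,
    seed: int = 0,
    noise_rate: float = 0.01,
    rows: int = 48,
    cols: int = 54,
) -> list:
    """Labeled synthetic action videos: one class per archetype, with
    per-subject jitter shared across that subject's classes and trials."""
    dataset = []
    for s in range(n_subjects):
        for trial in range(n_trials):
            jit = _subject_jitter(seed, s, trial)
            for label, arch in enumerate(archetypes):
                spec = SyntheticActionSpec(
                    archetype=arch,
                    length=length,
                    rows=rows,
                    cols=cols,
                    phase=jit["phase"],
                    body_scale=jit["body_scale"],
                    col_offset=jit["col_offset"],
                    row_offset=jit["row_offset"],
                    noise_rate=noise_rate,
                    seed=jit["seed"] + label,
                )
                seq = generate_synthetic_action(spec)
                seq.label = label
                seq.subject = f"s{s:02d}"
                seq.name = f"s{s:02d}_t{trial}_{arch}"
                dataset.append(seq)
    return dataset


def make_order_discrimination_dataset(
    n_per_class: int = 20,
    length: int = 40,
    seed: int = 0,
    noise_rate: float = 0.01,
    archetype: str = "walk",
) -> list:
    """Two classes with identical per-sequence frame multisets: class 0 is
    the base archetype (default: walking left-to-right, the classic
    direction-discrimination task), class 1 the exact frame reversal of
    the same rendered video.  Only temporal order separates the classes."""
    pair = {"walk": "walk_back", "grow": "shrink"}
    if archetype not in pair:
        raise ValueError(f"no reversal partner defined for {archetype!r}")
    dataset = []
    for s in range(n_per_class):
        jit = _subject_jitter(seed, s, 0)
        common = dict(
            length=length,
            phase=jit["phase"],
            body_scale=jit["body_scale"],
            col_offset=jit["col_offset"],
            row_offset=jit["row_offset"],
            noise_rate=noise_rate,
            seed=jit["seed"],
        )
        fwd = generate_synthetic_action(SyntheticActionSpec(archetype=archetype, **common))
        rev = generate_synthetic_action(SyntheticActionSpec(archetype=pair[archetype], **common))
        fwd.label, rev.label = 0, 1
        fwd.subject = rev.subject = f"s{s:02d}"
        fwd.name, rev.name = f"s{s:02d}_fwd", f"s{s:02d}_rev"
        dataset.extend([fwd, rev])
    return dataset


def make_concatenated_dataset(
    base_dataset: list, spec: ConcatenationSpec = ConcatenationSpec()
) -> list:
    """All ordered pairs of base actions per subject, each followed by
    black frames (3 base actions x 9 subjects -> 81 composites)."""
    by_subject: dict = {}
    for seq in base_dataset:
        by_subject.setdefault(seq.subject, {})[seq.label] = seq
    out = []
    for subject in sorted(by_subject):
        actions = by_subject[subject]
        for a in sorted(actions):
            for b in sorted(actions):
                out.append(concatenate_actions(actions[a], actions[b], spec))
    return out


# ---------------------------------------------------------------------------
# splitting


def loso_splits(dataset) -> list:
    """Leave-one-subject-out folds: one (train, test) pair per subject."""
    subjects = sorted({seq.subject for seq in dataset})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for held_out in subjects:
        train = [s for s in dataset if s.subject != held_out]
        test = [s for s in dataset if s.subject == held_out]
        folds.append((train, test))
    return folds


def prepare_dataset(dataset, d: int) -> list:
    """Append d black frames to every sequence (delay-response inputs)."""
    return [append_black_frames(seq, d) for seq in dataset]
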