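"""Internal-dynamics analysis: activation traces, snapshot PCA, nested
cluster structure, linear readouts, and the top-layer time-constant
ablation.

The slow top layer (large tau) integrates over the whole episode, so its
state at the end of a concatenated action retains information about the
first action even though that action is no longer visible; the fast lower
layers track the instantaneous input.  These tools quantify that contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_score

from .architecture import ArchitectureSpec, with_top_tau
from .network import Parameters, forward_sequence
from .training import TrainingConfig, train
from .evaluation import evaluate_accuracy


@dataclass
class ActivationTrace:
    """Activations of a sampled unit subset in one conv layer over time."""

    layer: int  # index into the architecture's layer stack
    unit_indices: np.ndarray
    values: np.ndarray  # (units, T)
    label: int
    subject: str


def record_activations(
    params: Parameters,
    spec: ArchitectureSpec,
    seq,
    layers,
    unit_sample: int | None = None,
    seed: int = 0,
) -> list:
    """Per-step activations v of a seeded random unit subset of each
    requested convolutional layer (``unit_sample=None`` keeps all units)."""
    conv_positions = {li: pos for pos, li in enumerate(spec.conv_indices)}
    for li in layers:
        if li not in conv_positions:
            raise ValueError(f"layer {li} is not a convolutional layer")
    _, cache = forward_sequence(params, spec, seq.frames, cache=True)
    rng = np.random.default_rng(seed)
    traces = []
    for li in layers:
        V = cache.conv_activations(conv_positions[li])  # (T, units)
        n_units = V.shape[1]
        if unit_sample is None or unit_sample >= n_units:
            idx = np.arange(n_units)
        else:
            idx = np.sort(rng.choice(n_units, size=unit_sample, replace=False))
        traces.append(
            ActivationTrace(
                layer=li,
                unit_indices=idx,
                values=V[:, idx].T,
                label=seq.label,
                subject=seq.subject,
            )
        )
    return traces


def layer_snapshots(
    params: Parameters, spec: ArchitectureSpec, dataset, layer: int, step: int
) -> np.ndarray:
    """Activation vectors of one conv layer at a fixed (1-based) time step
    across sequences, shaped (n_sequences, n_units)."""
    pos = {li: p for p, li in enumerate(spec.conv_indices)}[layer]
    rows = []
    for seq in dataset:
        if step > seq.T:
            raise ValueError(f"snapshot step {step} exceeds sequence length {seq.T}")
        _, cache = forward_sequence(params, spec, seq.frames, cache=True)
        rows.append(cache.conv_activations(pos)[step - 1])
    return np.stack(rows)


def mean_step_change(params, spec, dataset, layer: int) -> float:
    """Mean absolute per-step activation change of one conv layer,
    averaged over units, steps, and sequences.  Slow layers (large tau)
    score lower than fast layers on the same input."""
    pos = {li: p for p, li in enumerate(spec.conv_indices)}[layer]
    vals = []
    for seq in dataset:
        _, cache = forward_sequence(params, spec, seq.frames, cache=True)
        V = cache.conv_activations(pos)
        vals.append(float(np.mean(np.abs(np.diff(V, axis=0)))))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# snapshot PCA and cluster structure


@dataclass
class SnapshotEmbedding:
    """2-D principal-component coordinates of layer snapshots, components
    ordered by decreasing explained variance."""

    step: int
    layer: int
    coords: np.ndarray  # (n_sequences, n_components)
    explained_variance_ratio: np.ndarray


def snapshot_pca(
    snapshots: np.ndarray, n_components: int = 2, step: int = 0, layer: int = 0
) -> SnapshotEmbedding:
    """Centered (not standardized) PCA of per-sequence snapshots."""
    X = np.asarray(snapshots, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 snapshots for a PCA embedding")
    if np.allclose(X, X[0]):
        warnings.warn("all snapshots identical; embedding has zero variance", stacklevel=2)
        return SnapshotEmbedding(
            step, layer, np.zeros((X.shape[0], n_components)), np.zeros(n_components)
        )
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    if k < n_components:
        coords = np.pad(coords, ((0, 0), (0, n_components - k)))
    evr = np.pad(pca.explained_variance_ratio_, (0, n_components - k))
    return SnapshotEmbedding(step, layer, coords, evr)


def cluster_structure_summary(coords, first_labels, second_labels) -> dict:
    """Nested-cluster report: silhouette of the coarse grouping (by second
    action) and the mean within-coarse-group silhouette of the fine
    grouping (by first action).  A nested geometry gives
    coarse > fine > 0."""
    coords = np.asarray(coords, dtype=float)
    first = np.asarray(first_labels)
    second = np.asarray(second_labels)
    if len(set(second.tolist())) < 2:
        raise ValueError("need at least 2 coarse (second-action) groups")
    coarse = float(silhouette_score(coords, second))
    fines = []
    for g in np.unique(second):
        sel = second == g
        labels = first[sel]
        if len(set(labels.tolist())) < 2 or sel.sum() <= len(set(labels.tolist())):
            continue
        fines.append(float(silhouette_score(coords[sel], labels)))
    if not fines:
        raise ValueError("need at least 2 fine (first-action) groups within a coarse group")
    fine = float(np.mean(fines))
    return {"coarse": coarse, "fine": fine, "nested": coarse > fine > 0.0}


# ---------------------------------------------------------------------------
# linear readout of remembered context


def snapshot_readout_accuracy(
    params,
    spec,
    dataset,
    layer: int,
    step: int,
    labels,
    test_subjects,
    seed: int = 0,
) -> float:
    """Accuracy of a logistic-regression readout of layer snapshots,
    trained on all subjects except ``test_subjects`` and scored on them.

    Used with first-action labels on concatenated sequences: an
    above-chance score on the final-step top-layer snapshot demonstrates
    that the slow layer still carries the no-longer-visible first action.
    """
    X = layer_snapshots(params, spec, dataset, layer, step)
    y = np.asarray(labels)
    subjects = np.asarray([s.subject for s in dataset])
    test_mask = np.isin(subjects, list(test_subjects))
    if not test_mask.any() or test_mask.all():
        raise ValueError("test subjects must be a proper non-empty subset")
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(X[~test_mask], y[~test_mask])
    return float(clf.score(X[test_mask], y[test_mask]))


def loso_readout_accuracy(
    params, spec, dataset, layer: int, step: int, labels, seed: int = 0
) -> float:
    """Leave-one-subject-out accuracy of the snapshot readout, averaged
    over folds (snapshots computed once)."""
    X = layer_snapshots(params, spec, dataset, layer, step)
    y = np.asarray(labels)
    subjects = np.asarray([s.subject for s in dataset])
    accs = []
    for held in np.unique(subjects):
        mask = subjects == held
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(X[~mask], y[~mask])
        accs.append(float(clf.score(X[mask], y[mask])))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# time-constant ablation


def time_constant_ablation(
    dataset,
    config: TrainingConfig,
    spec: ArchitectureSpec,
    taus=(100.0, 80.0, 60.0, 40.0, 20.0),
    splits=None,
    seeds=None,
) -> pd.DataFrame:
    """Retrain with the top conv layer's time constant swept over ``taus``
    (lower-layer time constants fixed), recording test accuracy after
    every epoch.

    ``splits`` is a list of (train, test) pairs (default: a single split
    is required from the caller via ``splits``); ``seeds`` defaults to
    the config seed.  Returns a tidy frame (tau, seed, split, epoch,
    accuracy), the accuracy-vs-epoch curves of the ablation figure.
    """
    from dataclasses import replace as _replace

    if splits is None:
        from .data import loso_splits

        splits = loso_splits(dataset)
    seeds = [config.seed] if seeds is None else list(seeds)
    rows = []
    for tau in taus:
        if tau < 1:
            raise ValueError(f"time constant must be >= 1, got {tau}")
        spec_tau = with_top_tau(spec, tau)
        for seed in seeds:
            cfg = _replace(config, seed=seed)
            for si, (train_set, test_set) in enumerate(splits):

                def record(epoch, params, _tau=tau, _seed=seed, _si=si, _test=test_set):
                    rows.append(
                        {
                            "tau": _tau,
                            "seed": _seed,
                            "split": _si,
                            "epoch": epoch,
                            "accuracy": evaluate_accuracy(params, spec_tau, _test, cfg.delay),
                        }
                    )

                train(train_set, cfg, spec_tau, callback=record)
    return pd.DataFrame(rows)


def ablation_summary(table: pd.DataFrame) -> pd.Series:
    """Best epoch of the split- and seed-averaged curve, per tau."""
    curve = table.groupby(["tau", "epoch"])["accuracy"].mean()
    return curve.groupby("tau").max()


# ---------------------------------------------------------------------------
# figures (lazy matplotlib import; used by the CLI and examples)


def plot_activation_raster(traces, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(traces), 1, figsize=(8, 2.2 * len(traces)), squeeze=False)
    for ax, tr in zip(axes[:, 0], traces):
        ax.imshow(tr.values, aspect="auto", cmap="RdBu_r", vmin=-1.7159, vmax=1.7159)
        ax.set_ylabel(f"layer {tr.layer}\nunits")
        ax.set_xlabel("time step")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca_scatter(embedding: SnapshotEmbedding, first_labels, second_labels, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = np.asarray(first_labels)
    second = np.asarray(second_labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = "osD^v<>ph"
    for sec in np.unique(second):
        for fi in np.unique(first):
            sel = (second == sec) & (first == fi)
            if sel.any():
                ax.scatter(
                    embedding.coords[sel, 0],
                    embedding.coords[sel, 1],
                    c=[plt.cm.tab10(int(sec) % 10)],
                    marker=markers[int(fi) % len(markers)],
                    label=f"2nd={sec}, 1st={fi}",
                    s=40,
                )
    ax.set_xlabel(f"PC1 ({embedding.explained_variance_ratio[0]:.0%})")
    ax.set_ylabel(f"PC2 ({embedding.explained_variance_ratio[1]:.0%})")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_accuracy_curves(table: pd.DataFrame, path, by: str = "tau") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for key, grp in table.groupby(by):
        curve = grp.groupby("epoch")["accuracy"].mean()
        ax.plot(curve.index, 100 * curve.values, label=f"{by}={key}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
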