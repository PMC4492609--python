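"""Delay-response classification and the evaluation protocol.

A sequence is classified by majority voting over the per-step argmax of
the output distribution during the final d (black-frame) steps only.
The protocol is leave-one-subject-out cross-validation repeated over
seeds: accuracy is recorded after every training epoch, averaged over
folds, then over seeds, and the maximum over epochs is reported, rounded
to one decimal place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .architecture import ArchitectureSpec
from .data import OcclusionSpec, VideoSequence, apply_occlusion, loso_splits
from .network import Parameters, forward_sequence
from .training import TrainingConfig, train


@dataclass
class EpisodeResult:
    """Per-step output trace and the vote-based decision for one episode."""

    probs: np.ndarray  # (T, C)
    votes: np.ndarray  # per-step argmax over the supervised window (d,)
    predicted: int
    true_label: int

    @property
    def correct(self) -> bool:
        return self.predicted == self.true_label


def vote_from_trace(window_probs: np.ndarray) -> int:
    """Majority vote over a (d, C) probability trace; ties broken by the
    larger summed probability over the window, then the lowest index."""
    votes = window_probs.argmax(axis=1)
    counts = np.bincount(votes, minlength=window_probs.shape[1])
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    sums = window_probs[:, tied].sum(axis=0)
    # argmax returns the first (lowest-index) maximum, giving the final tie-break
    return int(tied[np.argmax(sums)])


def classify_sequence(
    params: Parameters, spec: ArchitectureSpec, seq: VideoSequence, d: int
) -> EpisodeResult:
    """Classify one sequence (which must already carry its d black frames)
    from a reset state."""
    if d > seq.T:
        raise ValueError(f"d={d} exceeds sequence length {seq.T}")
    Y, _ = forward_sequence(params, spec, seq.frames)
    window = Y[-d:]
    return EpisodeResult(
        probs=Y,
        votes=window.argmax(axis=1),
        predicted=vote_from_trace(window),
        true_label=seq.label,
    )


def evaluate_accuracy(params, spec, dataset, d: int) -> float:
    """Fraction of sequences whose voted prediction matches the label."""
    if not dataset:
        raise ValueError("empty evaluation dataset")
    hits = sum(classify_sequence(params, spec, s, d).correct for s in dataset)
    return hits / len(dataset)


# ---------------------------------------------------------------------------
# protocol


@dataclass
class ProtocolReport:
    """Accuracy per (fold, seed, epoch) plus the aggregation convention:
    mean over folds, then mean over seeds, then max over epochs."""

    table: pd.DataFrame  # columns: fold, seed, epoch, accuracy

    def per_epoch_curve(self) -> pd.Series:
        """Mean over folds then seeds, indexed by epoch."""
        per_seed = self.table.groupby(["seed", "epoch"])["accuracy"].mean()
        return per_seed.groupby("epoch").mean()

    def aggregate(self) -> float:
        """Best epoch of the fold- and seed-averaged curve, one decimal
        place, on a 0-100 scale."""
        return round(float(self.per_epoch_curve().max()) * 100.0, 1)


def run_protocol(
    dataset,
    config: TrainingConfig,
    spec: ArchitectureSpec,
    seeds,
    folds=None,
) -> ProtocolReport:
    """Leave-one-subject-out protocol over multiple seeds.

    ``dataset`` sequences must already carry their black frames.  Test
    accuracy is recorded after every epoch of every fold.  Custom
    ``folds`` (list of (train, test) pairs) may replace the LOSO split.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    if folds is None:
        folds = loso_splits(dataset)
    rows = []
    for seed in seeds:
        cfg = replace(config, seed=seed)
        for fold_idx, (train_set, test_set) in enumerate(folds):

            def record(epoch, params, _fold=fold_idx, _seed=seed, _test=test_set):
                rows.append(
                    {
                        "fold": _fold,
                        "seed": _seed,
                        "epoch": epoch,
                        "accuracy": evaluate_accuracy(params, spec, _test, cfg.delay),
                    }
                )

            try:
                train(train_set, cfg, spec, callback=record)
            except Exception as exc:
                raise RuntimeError(f"fold {fold_idx}, seed {seed}: {exc}") from exc
    return ProtocolReport(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# occlusion sweep


def occlusion_sweep(
    models,
    spec: ArchitectureSpec,
    d: int,
    widths=(0, 5, 10, 15, 20, 25, 30, 35, 40),
    gap: int = 5,
    speed: int = 2,
) -> pd.DataFrame:
    """Accuracy versus stripe width for already-trained models.

    ``models`` is a list of (params, test_set) pairs, each test set
    already carrying its black frames; no retraining and no max-over-
    epochs is involved.  Width 0 reproduces the unoccluded accuracy.
    Returns a tidy frame with columns width, model, accuracy.
    """
    rows = []
    for w in widths:
        if speed > 0 and w % speed:
            warnings.warn(
                f"bar width {w} is not a multiple of the stripe step {speed}; "
                "the mask phase never realigns exactly",
                stacklevel=2,
            )
        occ = OcclusionSpec(bar_width=int(w), gap=gap, speed=speed)
        for mi, (params, test_set) in enumerate(models):
            occluded = [apply_occlusion(s, occ) for s in test_set]
            rows.append(
                {
                    "width": int(w),
                    "model": mi,
                    "accuracy": evaluate_accuracy(params, spec, occluded, d),
                }
            )
    return pd.DataFrame(rows)


def occlusion_curve(sweep: pd.DataFrame) -> pd.Series:
    """Model-averaged accuracy per width."""
    return sweep.groupby("width")["accuracy"].mean()
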