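"""Subsample → fit → rank → replicate procedure over a voxel design matrix.

The engine draws ``M`` case/feature subsamples, fits the stacked ensemble on
each with internal cross-validation, ranks features by how often they appear
in the best-scoring subsamples, validates nested top-k models, merges
replications, and provides the subject-level external split.

Determinism: every subsample's indices and fit seed derive from the spec seed
through a fixed-order spawn, so parallel or reordered execution cannot change
the result of the order-independent reductions downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import stacking
from .io_wrangle import VoxelMatrix
from .metrics_report import ClassificationMetrics, confusion_metrics
from .stacking import FAST_LIBRARY, fit_superlearner

__all__ = [
    "SubsampleSpec",
    "SubsampleRecord",
    "FeatureRanking",
    "draw_subsamples",
    "run_cbda",
    "rank_features",
    "nested_topk",
    "run_replications",
    "external_split",
]


@dataclass(frozen=True)
class SubsampleSpec:
    """Subsampling design.

    ``csr`` and ``fsr`` are absolute row/column counts per subsample (the
    originating protocol calls them "rates" but sets them to whole counts).
    ``top_fraction`` is the share of subsamples, by accuracy, whose features
    are counted; ``k`` the reported top-feature list length; ``r`` the number
    of replications merged by :func:`run_replications`.
    """

    m: int = 5000
    csr: int = 0  # 0 → all rows
    fsr: int = 20
    top_fraction: float = 0.05
    k: int = 50
    r: int = 5
    folds: int = 10
    seed: int = 0
    normalize_counts: bool = False
    #: share one fold assignment across subsamples (paired comparison);
    #: meaningful when csr = n, where every subsample sees the same rows
    paired_folds: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.k < 1 or self.r < 1:
            raise ValueError("k and r must be >= 1")


@dataclass
class SubsampleRecord:
    """One subsample's membership and its ensemble CV accuracy."""

    index: int
    rows: np.ndarray
    features: np.ndarray  # original flat voxel ids
    accuracy: float
    seed: int

    def __post_init__(self) -> None:
        if len(np.unique(self.rows)) != len(self.rows):
            raise ValueError("duplicate rows in subsample")
        if len(np.unique(self.features)) != len(self.features):
            raise ValueError("duplicate features in subsample")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy out of [0, 1]")


@dataclass
class FeatureRanking:
    """Features ordered by frequency among the top-ranked subsamples.

    Ties break by total appearance count (descending), then feature id
    (ascending).  ``entries`` holds ``(feature_id, top_count, total_count)``.
    """

    entries: list[tuple[int, int, int]]
    n_top_records: int
    n_records: int

    @property
    def feature_ids(self) -> np.ndarray:
        return np.array([fid for fid, _, _ in self.entries], dtype=int)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "top_count", "total_count"])


def _stratified_rows(y: np.ndarray, csr: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``csr`` rows without replacement, preserving the class ratio ±1."""
    n = len(y)
    classes = np.unique(y)
    exact = {c: csr * (y == c).sum() / n for c in classes}
    take = {c: int(math.floor(v)) for c, v in exact.items()}
    remainders = sorted(classes, key=lambda c: exact[c] - take[c], reverse=True)
    for c in remainders:
        if sum(take.values()) >= csr:
            break
        take[c] += 1
    picks = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        picks.append(rng.choice(idx, size=min(take[c], len(idx)), replace=False))
    return np.sort(np.concatenate(picks))


def draw_subsamples(
    n: int, p: int, spec: SubsampleSpec, rng: np.random.Generator, y=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``spec.m`` (rows, features) index pairs.

    Rows are outcome-stratified without replacement; features are uniform
    without replacement.
    """
    csr = spec.csr or n
    if not 1 <= csr <= n:
        raise ValueError(f"csr={csr} invalid for n={n}")
    if not 1 <= spec.fsr <= p:
        raise ValueError(f"fsr={spec.fsr} invalid for p={p}")
    y = np.zeros(n, dtype=int) if y is None else np.asarray(y)
    pairs = []
    for _ in range(spec.m):
        rows = _stratified_rows(y, csr, rng)
        cols = np.sort(rng.choice(p, size=spec.fsr, replace=False))
        pairs.append((rows, cols))
    return pairs


def run_cbda(
    matrix: VoxelMatrix,
    spec: SubsampleSpec,
    library=FAST_LIBRARY,
) -> list[SubsampleRecord]:
    """Fit the stacked ensemble on every subsample and record its accuracy.

    Accuracy is the out-of-fold ensemble classification accuracy *within* the
    subsample (internal cross-validation).  A subsample that comes out
    single-class is redrawn once, then skipped with a warning.
    """
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("matrix must contain both outcome classes")
    rng = np.random.default_rng(spec.seed)
    if spec.paired_folds and (spec.csr == 0 or spec.csr == matrix.n_images):
        # identical rows in every subsample: evaluate them against one common
        # fold assignment so accuracies are directly comparable
        fit_seeds = np.full(spec.m, spec.seed)
    else:
        fit_seeds = rng.integers(0, 2**31 - 1, size=spec.m)
    pairs = draw_subsamples(matrix.n_images, matrix.n_voxels, spec, rng, y=y)
    records: list[SubsampleRecord] = []
    for m, (rows, cols) in enumerate(pairs):
        if len(np.unique(y[rows])) < 2:
            rows = _stratified_rows(y, spec.csr or matrix.n_images, rng)
            if len(np.unique(y[rows])) < 2:
                warnings.warn(f"subsample {m} single-class after redraw; skipped")
                continue
        fit = fit_superlearner(
            matrix.X[np.ix_(rows, cols)],
            y[rows],
            library=library,
            V=spec.folds,
            seed=int(fit_seeds[m]),
        )
        records.append(
            SubsampleRecord(
                index=m,
                rows=rows,
                features=matrix.col_flat[cols],
                accuracy=fit.cv_accuracy,
                seed=int(fit_seeds[m]),
            )
        )
    return records


def rank_features(records: list[SubsampleRecord], spec: SubsampleSpec) -> FeatureRanking:
    """Count feature occurrences among the best ``ceil(top_fraction * M)`` records.

    Accuracy ties break by draw order (earlier subsample wins).  With
    ``spec.normalize_counts`` the primary sort key becomes
    ``top_count / total_count`` instead of the raw top count.
    """
    if not records:
        raise ValueError("no subsample records to rank")
    n_top = max(1, math.ceil(spec.top_fraction * len(records)))
    order = sorted(range(len(records)), key=lambda i: (-records[i].accuracy, i))
    top = [records[i] for i in order[:n_top]]

    top_counts: dict[int, int] = {}
    total_counts: dict[int, int] = {}
    for rec in records:
        for fid in rec.features:
            total_counts[int(fid)] = total_counts.get(int(fid), 0) + 1
    for rec in top:
        for fid in rec.features:
            top_counts[int(fid)] = top_counts.get(int(fid), 0) + 1

    if spec.normalize_counts:
        key = lambda fid: (-top_counts[fid] / total_counts[fid], -total_counts[fid], fid)
    else:
        key = lambda fid: (-top_counts[fid], -total_counts[fid], fid)
    ordered = sorted(top_counts, key=key)
    entries = [(fid, top_counts[fid], total_counts[fid]) for fid in ordered]
    return FeatureRanking(entries=entries, n_top_records=n_top, n_records=len(records))


@dataclass
class TopkResult:
    ks: np.ndarray
    metrics: list[ClassificationMetrics]
    best_k: int

    @property
    def accuracy(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.metrics])

    @property
    def sensitivity(self) -> np.ndarray:
        return np.array([m.sensitivity for m in self.metrics])

    @property
    def specificity(self) -> np.ndarray:
        return np.array([m.specificity for m in self.metrics])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def nested_topk(
    matrix: VoxelMatrix,
    ranking: FeatureRanking,
    library=FAST_LIBRARY,
    kmax: int = 50,
    seed: int = 0,
    V: int = 10,
) -> TopkResult:
    """Internal-CV metrics of the ensemble restricted to the top-k voxels.

    ``best_k`` is the smallest k attaining the maximum accuracy — the
    overfitting check on the selected feature path.
    """
    if len(ranking) < 1:
        raise ValueError("ranking is empty")
    if kmax > len(ranking):
        warnings.warn(f"kmax={kmax} exceeds ranking length {len(ranking)}; truncated")
        kmax = len(ranking)
    cols_all = matrix.columns_of(ranking.feature_ids[:kmax])
    ks = np.arange(1, kmax + 1)
    metrics = []
    for k in ks:
        fit = fit_superlearner(
            matrix.X[:, cols_all[:k]], matrix.y, library=library, V=V, seed=seed + int(k)
        )
        y_pred = (fit.oof_pred >= 0.5).astype(int)
        metrics.append(confusion_metrics(matrix.y, y_pred))
    acc = np.array([m.accuracy for m in metrics])
    best_k = int(ks[int(np.argmax(acc))])
    return TopkResult(ks=ks, metrics=metrics, best_k=best_k)


@dataclass
class ReplicationResult:
    top_lists: list[np.ndarray]
    merged: np.ndarray  # concatenation, not deduplicated
    overlap_fraction: float
    rankings: list[FeatureRanking]


def run_replications(
    matrix: VoxelMatrix,
    spec: SubsampleSpec,
    library=FAST_LIBRARY,
) -> ReplicationResult:
    """R independent runs (seeds ``seed+1 .. seed+R``) merged without dedup.

    ``overlap_fraction`` is the share of distinct voxels that appear in the
    top list of at least two replications (0 by convention when R = 1).
    """
    top_lists, rankings = [], []
    for r in range(1, spec.r + 1):
        rep_spec = replace(spec, seed=spec.seed + r)
        ranking = rank_features(run_cbda(matrix, rep_spec, library), rep_spec)
        rankings.append(ranking)
        top_lists.append(ranking.feature_ids[: spec.k])
    merged = np.concatenate(top_lists) if top_lists else np.array([], dtype=int)
    if spec.r == 1:
        overlap = 0.0
    else:
        seen: dict[int, int] = {}
        for lst in top_lists:
            for fid in np.unique(lst):
                seen[int(fid)] = seen.get(int(fid), 0) + 1
        overlap = sum(1 for c in seen.values() if c >= 2) / len(seen) if seen else 0.0
    return ReplicationResult(
        top_lists=top_lists, merged=merged, overlap_fraction=float(overlap),
        rankings=rankings,
    )


def external_split(
    row_meta: pd.DataFrame,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level validation/training split, stratified by group and sex.

    Per (group, sex) stratum, ``round(fraction * n_subjects)`` subjects go to
    validation; within a stratum, subjects with fewer sessions are preferred
    (randomly among equals) so validation image counts stay comparable across
    subjects.  Returns (train row indices, validation row indices).
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    meta = row_meta.reset_index(drop=True)
    subj = (
        meta.groupby(["subject_id", "group", "sex"], sort=True)
        .size()
        .rename("n_rows")
        .reset_index()
    )
    subj["migraine"] = subj["group"].isin(["EM", "CM"]).astype(int)
    for cls in (0, 1):
        if (subj["migraine"] == cls).sum() < 2:
            raise ValueError("need at least two subjects per class to split")

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    val_per_class = {0: 0, 1: 0}
    for (group, sex), block in subj.groupby(["group", "sex"], sort=True):
        n_take = int(round(validation_fraction * len(block)))
        if n_take == 0:
            continue
        tiebreak = rng.permutation(len(block))
        order = sorted(range(len(block)),
                       key=lambda i: (block["n_rows"].iloc[i], tiebreak[i]))
        picked = block.iloc[order[:n_take]]
        chosen.extend(picked["subject_id"].tolist())
        val_per_class[int(picked["migraine"].iloc[0])] += n_take
    for cls, label in ((0, "healthy"), (1, "migraine")):
        if val_per_class[cls] == 0:
            raise ValueError(
                f"stratum too small: no {label} subjects drawn into validation; "
                "increase the fraction or the cohort"
            )
    val_mask = meta["subject_id"].isin(chosen).to_numpy()
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)
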