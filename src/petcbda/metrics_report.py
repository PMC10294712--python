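"""Classification metrics with exact binomial CIs and ROI frequency tables."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

from .io_wrangle import flat_to_ijk
from .synthetic_pet import LabeledAtlas, full_label_name

__all__ = [
    "ClassificationMetrics",
    "confusion_metrics",
    "exact_binomial_ci",
    "roi_frequency",
    "report_run",
]


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Clopper–Pearson interval from beta quantiles.

    Endpoints are exact; rounding (4 decimals) happens only at presentation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError(f"successes={successes} outside [0, {n}]")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


@dataclass
class ClassificationMetrics:
    """Confusion counts and derived rates for a binary task.

    ``sensitivity`` / ``specificity`` are the class-conditional correct rates
    for the positive / negative class under ``positive_label``; reports print
    both conventions since published tables differ on which class is
    "positive".
    """

    n: int
    n_pos: int
    n_neg: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ci_low: float
    ci_high: float
    positive_label: int = 1

    def __post_init__(self) -> None:
        if self.tp + self.tn + self.fp + self.fn != self.n:
            raise ValueError("confusion counts must sum to n")
        if not (self.ci_low <= self.accuracy <= self.ci_high):
            raise ValueError("CI must bracket the accuracy")

    @property
    def correct(self) -> int:
        return self.tp + self.tn

    def swapped(self) -> "ClassificationMetrics":
        """Same confusion matrix with the class roles exchanged."""
        return ClassificationMetrics(
            n=self.n, n_pos=self.n_neg, n_neg=self.n_pos,
            tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp,
            accuracy=self.accuracy,
            sensitivity=self.specificity, specificity=self.sensitivity,
            ci_low=self.ci_low, ci_high=self.ci_high,
            positive_label=1 - self.positive_label,
        )


def confusion_metrics(y_true, y_pred, positive_label: int = 1,
                      level: float = 0.95) -> ClassificationMetrics:
    """Confusion counts, accuracy with exact CI, and class-conditional rates."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    n = len(y_true)
    pos = y_true == positive_label
    neg = ~pos
    tp = int(np.sum(pos & (y_pred == positive_label)))
    fn = int(pos.sum() - tp)
    tn = int(np.sum(neg & (y_pred != positive_label)))
    fp = int(neg.sum() - tn)
    accuracy = (tp + tn) / n
    if pos.sum() == 0:
        warnings.warn("no positive-class rows: sensitivity undefined")
        sens = float("nan")
    else:
        sens = tp / pos.sum()
    if neg.sum() == 0:
        warnings.warn("no negative-class rows: specificity undefined")
        spec = float("nan")
    else:
        spec = tn / neg.sum()
    lo, hi = exact_binomial_ci(tp + tn, n, level=level)
    return ClassificationMetrics(
        n=n, n_pos=int(pos.sum()), n_neg=int(neg.sum()),
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, sensitivity=sens, specificity=spec,
        ci_low=lo, ci_high=hi, positive_label=positive_label,
    )


def roi_frequency(
    feature_ids,
    atlas: LabeledAtlas,
    level: str = "roi",
) -> pd.DataFrame:
    """Count merged top-list voxels per ROI (or subregion) name.

    Percentages are relative to the full merged-list length, so labelled rows
    sum to at most 100; voxels outside every atlas label are reported under
    ``unlabeled``.  Sorted by percentage descending, then name.
    """
    if level not in ("roi", "subregion"):
        raise ValueError("level must be 'roi' or 'subregion'")
    feature_ids = np.asarray(feature_ids, dtype=int)
    cols = ["name", "count", "pct"]
    if feature_ids.size == 0:
        return pd.DataFrame(columns=cols)
    ijk = flat_to_ijk(feature_ids, atlas.grid.dims)
    labels = atlas.labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    counts: dict[str, int] = {}
    for lab in labels:
        lab = int(lab)
        if lab == 0 or lab not in atlas.label_table:
            name = "unlabeled"
        else:
            roi, sub = atlas.label_table[lab]
            name = roi if level == "roi" else full_label_name(roi, sub)
        counts[name] = counts.get(name, 0) + 1
    total = len(feature_ids)
    rows = [(name, c, 100.0 * c / total) for name, c in counts.items()]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(rows, columns=cols)


def _fmt_metrics_block(title: str, m: ClassificationMetrics) -> str:
    sw = m.swapped()
    return "\n".join(
        [
            title,
            f"  n = {m.n} ({m.n_pos} positive / {m.n_neg} negative, "
            f"positive label = {m.positive_label})",
            f"  Accuracy: {m.accuracy:.4f}",
            f"  95% CI: ({m.ci_low:.4f}, {m.ci_high:.4f})",
            f"  Sensitivity: {m.sensitivity:.4f}   Specificity: {m.specificity:.4f}",
            f"  (swapped convention — Sensitivity: {sw.sensitivity:.4f}   "
            f"Specificity: {sw.specificity:.4f})",
        ]
    )


def _fmt_table(df: pd.DataFrame, floatfmt: str = "{:.4f}") -> str:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(floatfmt.format)
    return df.to_string(index=False)


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()[:12]


def report_run(
    replication_metrics: list[ClassificationMetrics],
    topk_tables: list[pd.DataFrame],
    frequency_tables: dict[str, pd.DataFrame],
    config_text: str = "",
    seeds: dict | None = None,
) -> str:
    """Assemble the plain-text run report.

    Deterministic for identical inputs (no timestamps), so regeneration from
    saved tables is bit-identical.
    """
    if not replication_metrics:
        raise ValueError("missing input: replication_metrics")
    if not frequency_tables:
        raise ValueError("missing input: frequency_tables")
    parts = ["=== run report ===", f"config sha256: {config_hash(config_text)}"]
    if seeds:
        parts.append("seeds: " + ", ".join(f"{k}={v}" for k, v in sorted(seeds.items())))
    parts.append("")
    for r, m in enumerate(replication_metrics, start=1):
        parts.append(_fmt_metrics_block(f"Replication {r}", m))
        parts.append("")
    for r, table in enumerate(topk_tables, start=1):
        parts.append(f"Nested top-k metrics, replication {r}:")
        parts.append(_fmt_table(table))
        parts.append("")
    for name, table in sorted(frequency_tables.items()):
        parts.append(f"Frequency table ({name}):")
        parts.append(_fmt_table(table) if len(table) else "  (empty)")
        parts.append("")
    if config_text:
        parts.append("--- config echo ---")
        parts.append(config_text.rstrip())
        parts.append("")
    return "\n".join(parts)
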