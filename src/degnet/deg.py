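"""Differential-expression selection.

Per-gene log2 fold changes (difference of condition means on the log2
scale), Welch two-sample t-test p-values, the compound selection rule
|fold change| > 2 with raw p < 0.01 (strict inequalities on both), Venn
partitioning of DEG sets between contrasts, and up/down tallies. No
multiple-testing correction is applied: the compound threshold is used
as-is, with a notice logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContrastError, SchemaError

logger = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


@dataclass
class ExpressionMatrix:
    """Log2 intensities, genes x samples, with a sample -> condition design."""

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate gene IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate sample IDs in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise SchemaError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise SchemaError(f"samples missing from design: {missing}")
        self.design = self.design.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design:
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s, c in self.design.items() if c == condition]
        if not out:
            raise ContrastError(f"condition {condition!r} absent from design")
        return out


@dataclass(frozen=True)
class Contrast:
    treatment: str
    reference: str

    def __post_init__(self) -> None:
        if self.treatment == self.reference:
            raise ContrastError("treatment and reference must differ")

    def __str__(self) -> str:  # used in file names and log lines
        return f"{self.treatment}_vs_{self.reference}"


@dataclass(frozen=True)
class DegThresholds:
    """Compound DEG rule: linear fold change > fold_change_min AND p < p_max."""

    fold_change_min: float = 2.0
    p_max: float = 0.01

    def __post_init__(self) -> None:
        if not self.fold_change_min > 1:
            raise SchemaError("fold_change_min must be > 1")
        if not 0 < self.p_max < 1:
            raise SchemaError("p_max must be in (0, 1)")


@dataclass
class DegResult:
    """Selection outcome for one contrast."""

    contrast: Contrast
    table: pd.DataFrame  # columns: log2fc, p, is_deg, direction (index = gene)
    thresholds: DegThresholds = field(default_factory=DegThresholds)

    @property
    def deg_set(self) -> frozenset:
        return frozenset(self.table.index[self.table["is_deg"]])

    @property
    def directions(self) -> pd.Series:
        return self.table.loc[self.table["is_deg"], "direction"]


def log2_fold_change(m: ExpressionMatrix, c: Contrast) -> pd.Series:
    """Difference of per-condition means on the log2 scale (treatment - reference)."""
    t = m.values[m.samples_for(c.treatment)].mean(axis=1)
    r = m.values[m.samples_for(c.reference)].mean(axis=1)
    out = t - r
    out.name = "log2fc"
    return out

def gene_pvalues(m: ExpressionMatrix, c: Contrast) -> pd.Series:
    """Two-sided Welch t-test per gene on log2 values.

    Degenerate zero-variance cases are defined explicitly: equal means
    with no variance in either group give p = 1; unequal means with no
    variance give the smallest positive float (perfect separation).
    """
    t_cols = m.samples_for(c.treatment)
    r_cols = m.samples_for(c.reference)
    if len(t_cols) < 2 or len(r_cols) < 2:
        raise ContrastError("each condition needs >= 2 replicates for testing")
    a = m.values[t_cols].to_numpy()
    b = m.values[r_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    no_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = a.mean(axis=1) == b.mean(axis=1)
    p = np.where(no_var & equal_means, 1.0, p)
    p = np.where(no_var & ~equal_means, _TINY_P, p)
    p = np.where(np.isnan(p) & equal_means, 1.0, p)  # 0/0 t-statistic
    p = np.where(p == 0.0, _TINY_P, p)
    return pd.Series(p, index=m.values.index, name="p")


def select_degs(
    log2fc: pd.Series,
    p: pd.Series,
    th: DegThresholds = DegThresholds(),
    contrast: Contrast | None = None,
) -> DegResult:
    """Apply the compound threshold with strict inequalities on both criteria.

    A gene is a DEG iff |log2fc| > log2(fold_change_min) and p < p_max;
    genes on either boundary are excluded, as are genes with NaN in
    either statistic (dropped with a warning).
    """
    if not log2fc.index.equals(p.index):
        raise SchemaError("log2fc and p must be aligned on the same genes")
    nan_mask = log2fc.isna() | p.isna()
    if nan_mask.any():
        logger.warning(
            "excluding %d gene(s) with NaN fold change or p-value", int(nan_mask.sum())
        )
    is_deg = (
        (log2fc.abs() > np.log2(th.fold_change_min)) & (p < th.p_max) & ~nan_mask
    )
    direction = pd.Series(
        np.where(log2fc > 0, "up", "down"), index=log2fc.index, name="direction"
    ).where(is_deg, other="")
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "is_deg": is_deg, "direction": direction}
    )
    logger.info(
        "selected %d DEGs of %d genes (|FC| > %g, p < %g, no multiplicity correction)",
        int(is_deg.sum()),
        len(table),
        th.fold_change_min,
        th.p_max,
    )
    return DegResult(
        contrast=contrast if contrast is not None else Contrast("treatment", "reference"),
        table=table,
        thresholds=th,
    )


def partition_venn(a: frozenset | set, b: frozenset | set):
    """Disjoint partition of two DEG sets: (common, a_only, b_only)."""
    a, b = frozenset(a), frozenset(b)
    return a & b, a - b, b - a


def updown_counts(r: DegResult) -> tuple[int, int]:
    """Number of up- and down-regulated DEGs (by sign of log2 fold change)."""
    d = r.directions
    return int((d == "up").sum()), int((d == "down").sum())
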