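"""Two-group differential expression and cross-cohort pattern intersection.

The default per-gene test is Welch's two-sample t on the provided
(log2) scale; the log2 fold change is ``mean(B) - mean(A)``.  P-values
are adjusted with the Benjamini–Hochberg step-up rule.  Gene lists are
formed by taking the top-K most significant up- and down-regulated
genes per cohort (gated on adjusted p < alpha) and intersecting them
across cohorts, yielding the common up/down lists that feed enrichment,
PPI and key-gene stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleLabels, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "two_group_test",
    "bh_adjust",
    "select_top_k",
    "significant_genes",
    "common_pattern_genes",
    "CommonGeneLists",
]


def two_group_test(matrix: ExpressionMatrix, labels: SampleLabels) -> pd.DataFrame:
    """Welch two-sample t-test per gene, condition B versus condition A.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean(B)
    - mean(A)), ``stat``, ``pvalue`` and ``padj`` (Benjamini–Hochberg).
    A gene with zero variance in both groups and equal means gets
    ``stat = 0, pvalue = 1``; zero variance with unequal means gets an
    infinite statistic and ``pvalue = 0``.
    """
    mask_a, mask_b = labels.condition_masks(matrix)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 3 or n_b < 3:
        raise ValidationError(
            f"both groups need >= 3 samples, got A={n_a}, B={n_b}"
        )
    xa = matrix.values[:, mask_a]
    xb = matrix.values[:, mask_b]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    log2fc = mb - ma

    se2 = va / n_a + vb / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = log2fc / np.sqrt(se2)
        df = se2**2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        )
    degenerate = se2 == 0
    equal = degenerate & (log2fc == 0)
    separated = degenerate & (log2fc != 0)
    pvalue = np.empty(matrix.n_genes)
    ok = ~degenerate
    pvalue[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), df[ok])
    stat[equal], pvalue[equal] = 0.0, 1.0
    stat[separated] = np.sign(log2fc[separated]) * np.inf
    pvalue[separated] = 0.0

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        },
        index=pd.Index(matrix.genes, name="gene"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved).

    Equivalent to ``min over j >= i of p_(j) * m / j`` on the sorted
    p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def significant_genes(
    de: pd.DataFrame, alpha: float = 0.05, fc_threshold: float | None = 2.0
) -> pd.DataFrame:
    """Rows passing the DEG definition: adjusted p < alpha and, when
    ``fc_threshold`` is given, fold change > threshold (|log2fc| >
    log2(threshold))."""
    keep = de["padj"] < alpha
    if fc_threshold is not None:
        keep &= de["log2fc"].abs() > np.log2(fc_threshold)
    return de.loc[keep]


def select_top_k(
    de: pd.DataFrame,
    k: int,
    direction: str,
    alpha: float = 0.05,
    fc_threshold: float | None = None,
) -> list[str]:
    """Top-k genes of one regulation direction, ranked by significance.

    Eligible genes have sign-consistent ``log2fc`` (up: > 0, down: < 0)
    and adjusted p < ``alpha``; ranking is by adjusted p ascending, ties
    broken by |log2fc| descending, then gene identifier.  Fewer than
    ``k`` genes may be returned.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    sign = 1.0 if direction == "up" else -1.0
    eligible = de.loc[(sign * de["log2fc"] > 0) & (de["padj"] < alpha)]
    if fc_threshold is not None:
        eligible = eligible.loc[eligible["log2fc"].abs() > np.log2(fc_threshold)]
    if eligible.empty:
        logger.warning("no %s-regulated gene passes adjusted p < %g", direction, alpha)
        return []
    frame = eligible.assign(_absfc=eligible["log2fc"].abs(), _gene=eligible.index)
    frame = frame.sort_values(
        ["padj", "_absfc", "_gene"], ascending=[True, False, True], kind="stable"
    )
    return list(frame.index[:k])


@dataclass
class CommonGeneLists:
    """Cross-cohort common up/down gene lists with provenance."""

    common_up: set[str]
    common_down: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.common_up & self.common_down
        if overlap:
            raise ValidationError(
                f"genes in both common_up and common_down: {sorted(overlap)[:5]}"
            )


def common_pattern_genes(
    lists_a: tuple[list[str], list[str]],
    lists_b: tuple[list[str], list[str]],
    k: int | None = None,
) -> CommonGeneLists:
    """Intersect per-cohort top-K (up, down) lists into common gene lists."""
    up_a, down_a = lists_a
    up_b, down_b = lists_b
    common_up = set(up_a) & set(up_b)
    common_down = set(down_a) & set(down_b)
    if not common_up and not common_down:
        logger.warning("cohort gene lists have empty intersections")
    return CommonGeneLists(
        common_up,
        common_down,
        provenance={
            "k": k,
            "sizes": {
                "up_a": len(up_a),
                "down_a": len(down_a),
                "up_b": len(up_b),
                "down_b": len(down_b),
            },
        },
    )
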