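"""Modular differential connectivity (MDC) and its permutation test.

For a module with member genes measured in two conditions, the
connectivity in a condition is the mean absolute Pearson correlation
over all unordered pairs of members, computed on that condition's
samples only.  The statistic is the ratio

    MDC = rbar_A / rbar_B,

so MDC > 1 means tighter co-regulation in condition A.  Significance is
assessed with a label-shuffling permutation test on |log2 MDC|: sample
condition labels are permuted (group sizes preserved), MDC recomputed,
and the empirical two-sided p-value uses a pseudocount,
``(1 + #{|log2 MDC_perm| >= |log2 MDC_obs|}) / (1 + n_perm)``.  The
same permutation sequence is applied to every module so cross-module
dependence is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleLabels, ValidationError
from .network import ModulePartition

logger = logging.getLogger(__name__)

__all__ = ["module_connectivity", "mdc_statistic", "mdc_permutation_test"]


def _mean_abs_corr(x: np.ndarray, context: str = "") -> float:
    """Mean |Pearson correlation| over unordered row pairs of ``x``.

    Rows with zero variance are excluded (their pairs are undefined);
    the exclusion is logged.  Raises when fewer than 2 usable rows
    remain.
    """
    sd = x.std(axis=1)
    usable = sd > 0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.warning("%s: excluded %d constant gene(s)", context or "connectivity", n_dropped)
    x = x[usable]
    if x.shape[0] < 2:
        raise ValidationError(
            f"{context or 'connectivity'}: fewer than 2 non-constant genes"
        )
    z = x - x.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    corr = np.clip(z @ z.T, -1.0, 1.0)
    g = corr.shape[0]
    iu = np.triu_indices(g, k=1)
    return float(np.abs(corr[iu]).mean())


def module_connectivity(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    partition: ModulePartition,
    module: int,
    condition: str,
) -> float:
    """Mean absolute pairwise correlation of a module in one condition."""
    if condition not in ("A", "B"):
        raise ValidationError(f"condition must be 'A' or 'B', got {condition!r}")
    members = partition.members(module)
    if len(members) < 3:
        raise ValidationError(f"module {module} has fewer than 3 genes")
    mask_a, mask_b = labels.condition_masks(matrix)
    mask = mask_a if condition == "A" else mask_b
    if mask.sum() < 4:
        raise ValidationError(f"condition {condition} has fewer than 4 samples")
    idx = matrix.gene_index(members)
    return _mean_abs_corr(
        matrix.values[np.ix_(idx, np.flatnonzero(mask))],
        context=f"module {module}/{condition}",
    )


def _per_module_indices(
    matrix: ExpressionMatrix, partition: ModulePartition
) -> dict[int, np.ndarray]:
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    out: dict[int, np.ndarray] = {}
    for m in range(1, partition.n_modules + 1):
        members = [g for g in partition.members(m) if g in gene_pos]
        out[m] = np.array([gene_pos[g] for g in members], dtype=int)
    return out


def _mdc_for_split(
    values: np.ndarray,
    module_idx: dict[int, np.ndarray],
    cols_a: np.ndarray,
    cols_b: np.ndarray,
) -> dict[int, tuple[float, float, float]]:
    out = {}
    for m, idx in module_idx.items():
        r_a = _mean_abs_corr(values[np.ix_(idx, cols_a)], context=f"module {m}/A")
        r_b = _mean_abs_corr(values[np.ix_(idx, cols_b)], context=f"module {m}/B")
        if r_b == 0:
            raise ValidationError(f"module {m}: zero connectivity in condition B")
        out[m] = (r_a, r_b, r_a / r_b)
    return out


def mdc_statistic(
    matrix: ExpressionMatrix, labels: SampleLabels, partition: ModulePartition
) -> pd.DataFrame:
    """Per-module MDC = rbar_A / rbar_B (no permutation p-value).

    Returns a DataFrame indexed by module with columns ``n_genes``,
    ``r_a``, ``r_b``, ``mdc`` and ``log2_mdc``.  Modules failing the
    preconditions (fewer than 3 genes) are reported with NaN values and
    a reason.
    """
    mask_a, mask_b = labels.condition_masks(matrix)
    if mask_a.sum() < 4 or mask_b.sum() < 4:
        raise ValidationError("each condition needs >= 4 samples for MDC")
    module_idx = _per_module_indices(matrix, partition)
    rows = []
    for m in range(1, partition.n_modules + 1):
        idx = module_idx[m]
        if idx.size < 3:
            rows.append((m, idx.size, np.nan, np.nan, np.nan, np.nan, "too few genes"))
            continue
        r_a = _mean_abs_corr(matrix.values[np.ix_(idx, np.flatnonzero(mask_a))], f"module {m}/A")
        r_b = _mean_abs_corr(matrix.values[np.ix_(idx, np.flatnonzero(mask_b))], f"module {m}/B")
        if r_b == 0:
            raise ValidationError(f"module {m}: zero connectivity in condition B")
        rows.append((m, idx.size, r_a, r_b, r_a / r_b, np.log2(r_a / r_b), ""))
    return pd.DataFrame(
        rows,
        columns=["module", "n_genes", "r_a", "r_b", "mdc", "log2_mdc", "note"],
    ).set_index("module")


def mdc_permutation_test(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    partition: ModulePartition,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    bh_across_modules: bool = False,
) -> pd.DataFrame:
    """MDC with a label-shuffling permutation p-value per module.

    Adds columns ``pvalue``, ``n_perm`` and ``significant`` (p < alpha)
    to the :func:`mdc_statistic` table.  ``bh_across_modules`` adds a
    ``padj`` column (Benjamini–Hochberg over modules) and bases the
    significance flag on it; the default follows the raw per-module
    0.05 convention.  Fully deterministic given ``seed``; the same
    permutation sequence is shared by all modules.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    result = mdc_statistic(matrix, labels, partition)
    mask_a, _ = labels.condition_masks(matrix)
    n_a = int(mask_a.sum())
    n = matrix.n_samples
    module_idx = {
        m: idx for m, idx in _per_module_indices(matrix, partition).items() if idx.size >= 3
    }
    observed = {m: abs(result.loc[m, "log2_mdc"]) for m in module_idx}
    exceed = {m: 0 for m in module_idx}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        cols_a, cols_b = perm[:n_a], perm[n_a:]
        for m, (_, _, ratio) in _mdc_for_split(
            matrix.values, module_idx, cols_a, cols_b
        ).items():
            if abs(np.log2(ratio)) >= observed[m]:
                exceed[m] += 1
    result["pvalue"] = [
        (1 + exceed[m]) / (1 + n_perm) if m in exceed else np.nan for m in result.index
    ]
    result["n_perm"] = n_perm
    if bh_across_modules:
        from .diffexpr import bh_adjust

        computed = result["pvalue"].notna()
        result["padj"] = np.nan
        result.loc[computed, "padj"] = bh_adjust(
            result.loc[computed, "pvalue"].to_numpy()
        )
        result["significant"] = result["padj"] < alpha
    else:
        result["significant"] = result["pvalue"] < alpha
    return result
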