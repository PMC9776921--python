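"""Weighted co-expression network construction and module detection.

The construction follows the standard weighted co-expression workflow on
an unsigned network: keep the most variable genes, raise |Pearson
correlation| to a soft-threshold power so the connectivity distribution
approaches scale-free, convert the adjacency to a topological overlap
matrix (TOM), cluster genes by average-linkage on TOM dissimilarity,
cut the tree into modules, and merge modules whose eigengenes are
nearly collinear.  Module eigengenes are the first principal component
of the standardized module submatrix; kME is the correlation of each
gene with each eigengene and defines hub genes at |kME| above a
threshold (0.85 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ModulePartition",
    "EigengeneMatrix",
    "variance_filter",
    "pick_soft_power",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "kme",
    "build_network",
]


@dataclass
class NetworkConfig:
    """Knobs of the network construction.

    ``soft_power`` may be a positive integer or ``"auto"`` (scale-free
    criterion over ``candidate_powers``).  ``merge_cut`` is the
    eigengene-dissimilarity threshold below which modules are merged —
    the tree cutoff for merging similar branches.  ``variance_keep_fraction``
    keeps the top fraction of genes by variance.
    """

    soft_power: int | str = 6
    min_module_size: int = 30
    merge_cut: float = 0.25
    variance_keep_fraction: float = 0.75
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20)
    r2_target: float = 0.8
    cut_height_fraction: float = 0.99

    def validate(self) -> None:
        if self.soft_power != "auto" and not (1 <= int(self.soft_power) <= 30):
            raise ValidationError("soft_power must be in [1, 30] or 'auto'")
        if not 0.0 < self.merge_cut < 1.0:
            raise ValidationError("merge_cut must be in (0, 1)")
        if not 0.0 < self.variance_keep_fraction <= 1.0:
            raise ValidationError("variance_keep_fraction must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")


@dataclass
class ModulePartition:
    """Gene-to-module assignment plus the clustering dendrogram.

    Module labels are contiguous ``1..M`` ordered by decreasing size;
    label 0 marks unassigned (background) genes.
    """

    genes: list[str]
    labels: np.ndarray
    linkage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.genes) != self.labels.size:
            raise ValidationError("genes and labels lengths differ")
        present = sorted(set(self.labels.tolist()) - {0})
        if present != list(range(1, len(present) + 1)):
            raise ValidationError(f"module labels must be contiguous 1..M, got {present}")

    @property
    def n_modules(self) -> int:
        return int(self.labels.max(initial=0))

    def module_sizes(self) -> dict[int, int]:
        return {m: int(np.sum(self.labels == m)) for m in range(1, self.n_modules + 1)}

    def members(self, module: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == module]

    def module_of(self) -> dict[str, int]:
        return {g: int(l) for g, l in zip(self.genes, self.labels)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"module": self.labels}, index=pd.Index(self.genes, name="gene"))


@dataclass
class EigengeneMatrix:
    """Per-module eigengene values across samples (unit-norm rows)."""

    modules: list[int]
    samples: list[str]
    values: np.ndarray  # modules x samples
    variance_explained: dict[int, float] = field(default_factory=dict)

    def eigengene(self, module: int) -> np.ndarray:
        return self.values[self.modules.index(module)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.T,
            index=pd.Index(self.samples, name="sample"),
            columns=[f"ME{m}" for m in self.modules],
        )


def variance_filter(matrix: ExpressionMatrix, keep_fraction: float) -> ExpressionMatrix:
    """Keep the ``ceil(keep_fraction * G)`` genes of highest variance.

    Ties at the cut are resolved by keeping the lexicographically
    smaller gene identifier.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValidationError("keep_fraction must be in (0, 1]")
    variances = matrix.values.var(axis=1, ddof=1)
    n_keep = int(np.ceil(keep_fraction * matrix.n_genes))
    if n_keep < 2:
        raise ValidationError("variance filter would leave fewer than 2 genes")
    order = sorted(range(matrix.n_genes), key=lambda i: (-variances[i], matrix.genes[i]))
    keep = sorted(order[:n_keep])  # preserve original row order
    return ExpressionMatrix(
        [matrix.genes[i] for i in keep], list(matrix.samples), matrix.values[keep]
    )


def adjacency(matrix: ExpressionMatrix, beta: int | float) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``a_ij = |cor(x_i, x_j)|^beta``.

    The diagonal is set to 0 so connectivity and TOM sums exclude
    self-adjacency.
    """
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    sd = matrix.values.std(axis=1)
    if np.any(sd == 0):
        bad = matrix.genes[int(np.argmax(sd == 0))]
        raise ValidationError(f"constant gene {bad!r}: correlation undefined")
    corr = np.corrcoef(matrix.values)
    a = np.abs(np.clip(corr, -1.0, 1.0)) ** beta
    a = (a + a.T) / 2.0  # corrcoef is only symmetric to rounding
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit.

    Bins the connectivity into equal-width bins, then regresses
    log10(bin frequency) on log10(mean bin connectivity); the R^2 is
    negated when the slope is positive (scale-free networks have a
    decreasing degree distribution).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_p.append(np.log10(mask.sum() / k.size))
    if len(log_k) < 3 or len(set(log_p)) < 2:
        return 0.0
    slope, _ = np.polyfit(log_k, log_p, 1)
    r = np.corrcoef(log_k, log_p)[0, 1]
    return float(-np.sign(slope) * r**2)


def pick_soft_power(
    matrix: ExpressionMatrix,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
) -> int:
    """Smallest power whose scale-free fit R^2 reaches ``r2_target``.

    Falls back to the argmax power with a warning when no candidate
    reaches the target.
    """
    if matrix.n_genes < 50:
        raise ValidationError("soft-power selection needs >= 50 genes")
    candidates = list(candidate_powers)
    if not candidates:
        raise ValidationError("candidate_powers must be non-empty")
    corr = np.corrcoef(matrix.values)
    np.fill_diagonal(corr, 0.0)
    abs_corr = np.abs(np.clip(corr, -1.0, 1.0))
    best_power, best_r2 = candidates[0], -np.inf
    for beta in candidates:
        k = (abs_corr**beta).sum(axis=0)
        r2 = scale_free_fit(k)
        if r2 >= r2_target:
            return int(beta)
        if r2 > best_r2:
            best_power, best_r2 = beta, r2
    logger.warning(
        "no candidate power reached scale-free R^2 >= %g; using %d (R^2 = %.3f)",
        r2_target,
        best_power,
        best_r2,
    )
    return int(best_power)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` and ``k_i = sum_u a_iu``; the diagonal is
    1 by convention.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if np.any((a < 0) | (a > 1)):
        raise ValidationError("adjacency values must lie in [0, 1]")
    l = a @ a
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengenes(
    matrix: ExpressionMatrix, partition: ModulePartition
) -> EigengeneMatrix:
    """First principal component of each module's standardized submatrix.

    Each gene is standardized across samples; the eigengene is the
    leading right-singular vector (unit norm over samples), with its
    sign oriented so the mean correlation with member genes is
    non-negative.  ``variance_explained`` is the leading singular
    value's share of the total variance.
    """
    gene_of = {g: i for i, g in enumerate(matrix.genes)}
    modules = sorted(set(partition.labels.tolist()) - {0})
    values = np.empty((len(modules), matrix.n_samples))
    varexp: dict[int, float] = {}
    for row, m in enumerate(modules):
        members = [g for g in partition.members(m) if g in gene_of]
        if len(members) < 2:
            raise ValidationError(f"module {m} has fewer than 2 genes in the matrix")
        x = matrix.values[[gene_of[g] for g in members]]
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = members[int(np.argmax(sd == 0))]
            raise ValidationError(f"zero-variance gene {bad!r} in module {m}")
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        member_cor = (z / np.linalg.norm(z, axis=1, keepdims=True)) @ eig
        if member_cor.mean() < 0:
            eig = -eig
        values[row] = eig
        varexp[m] = float(s[0] ** 2 / np.sum(s**2))
    return EigengeneMatrix(modules, list(matrix.samples), values, varexp)


def _merge_modules(
    matrix: ExpressionMatrix, labels: np.ndarray, genes: list[str], merge_cut: float
) -> np.ndarray:
    """Iteratively merge module pairs with eigengene dissimilarity < merge_cut."""
    labels = labels.copy()
    while True:
        present = sorted(set(labels.tolist()) - {0})
        if len(present) < 2:
            return labels
        part = ModulePartition(genes, _relabel(labels))
        eig = module_eigengenes(matrix, part)
        corr = np.corrcoef(eig.values)
        dissim = 1.0 - corr
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(np.argmin(dissim), dissim.shape)
        if dissim[i, j] >= merge_cut:
            return _relabel(labels)
        relabelled = _relabel(labels)
        relabelled[relabelled == eig.modules[j]] = eig.modules[i]
        labels = relabelled


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber non-zero labels contiguously by decreasing module size."""
    out = np.zeros_like(labels)
    sizes = {m: int(np.sum(labels == m)) for m in set(labels.tolist()) - {0}}
    ordered = sorted(sizes, key=lambda m: (-sizes[m], m))
    for new, old in enumerate(ordered, start=1):
        out[labels == old] = new
    return out


def detect_modules(
    tom_dissimilarity: np.ndarray,
    matrix: ExpressionMatrix,
    min_module_size: int = 30,
    merge_cut: float = 0.25,
    cut_height_fraction: float = 0.99,
) -> ModulePartition:
    """Hierarchical module detection on TOM dissimilarity.

    Average-linkage clustering of ``1 - TOM``; the tree is cut
    statically at ``cut_height_fraction`` of the maximum merge height
    (unrelated genes join only at the very top of a TOM dendrogram, so
    the cut isolates the co-expressed branches); clusters smaller than
    ``min_module_size`` are left unassigned (label 0); modules whose
    eigengenes are closer than ``merge_cut`` (1 - correlation) are then
    merged iteratively.  Labels are renumbered by decreasing size.
    """
    d = np.asarray(tom_dissimilarity, dtype=float)
    if d.shape != (matrix.n_genes, matrix.n_genes):
        raise ValidationError("dissimilarity shape does not match the matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("dissimilarity must be symmetric")
    dd = (d + d.T) / 2.0
    np.fill_diagonal(dd, 0.0)
    z = hierarchy.linkage(squareform(dd, checks=False), method="average")
    heights = z[:, 2]
    cut = cut_height_fraction * heights.max()
    raw = hierarchy.fcluster(z, t=cut, criterion="distance")
    labels = np.zeros(matrix.n_genes, dtype=int)
    for c in set(raw.tolist()):
        mask = raw == c
        if mask.sum() >= min_module_size:
            labels[mask] = c
    if labels.max(initial=0) == 0:
        logger.warning(
            "no cluster reaches min_module_size=%d; all genes unassigned",
            min_module_size,
        )
        return ModulePartition(list(matrix.genes), labels, z)
    labels = _relabel(labels)
    if labels.min() > 0 and len(set(labels.tolist())) == 1:
        logger.warning("all genes fall in a single module")
    labels = _merge_modules(matrix, labels, list(matrix.genes), merge_cut)
    return ModulePartition(list(matrix.genes), labels, z)


def kme(matrix: ExpressionMatrix, eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """Module membership: Pearson correlation of genes with eigengenes.

    Returns a genes x modules DataFrame (columns ``ME<m>``).  Genes with
    zero variance get kME 0.
    """
    if list(matrix.samples) != list(eigengenes.samples):
        raise ValidationError("matrix and eigengenes must share samples")
    x = matrix.values
    sd = x.std(axis=1)
    z = np.where(
        sd[:, None] > 0, (x - x.mean(axis=1, keepdims=True)), 0.0
    )
    norms = np.linalg.norm(z, axis=1)
    norms[norms == 0] = 1.0
    z = z / norms[:, None]
    e = eigengenes.values - eigengenes.values.mean(axis=1, keepdims=True)
    e = e / np.linalg.norm(e, axis=1, keepdims=True)
    table = np.clip(z @ e.T, -1.0, 1.0)
    return pd.DataFrame(
        table,
        index=pd.Index(matrix.genes, name="gene"),
        columns=[f"ME{m}" for m in eigengenes.modules],
    )


def build_network(
    matrix: ExpressionMatrix, config: NetworkConfig | None = None
) -> tuple[ExpressionMatrix, ModulePartition, EigengeneMatrix, pd.DataFrame, int]:
    """Run the full construction: filter, power, TOM, modules, eigengenes, kME.

    Returns ``(filtered_matrix, partition, eigengenes, kme_table, power)``.
    """
    config = config or NetworkConfig()
    config.validate()
    filtered = variance_filter(matrix, config.variance_keep_fraction)
    if config.soft_power == "auto":
        power = pick_soft_power(filtered, config.candidate_powers, config.r2_target)
    else:
        power = int(config.soft_power)
    a = adjacency(filtered, power)
    tom = topological_overlap(a)
    partition = detect_modules(
        1.0 - tom,
        filtered,
        min_module_size=config.min_module_size,
        merge_cut=config.merge_cut,
        cut_height_fraction=config.cut_height_fraction,
    )
    if partition.n_modules == 0:
        return filtered, partition, EigengeneMatrix([], list(filtered.samples), np.empty((0, filtered.n_samples))), pd.DataFrame(index=filtered.genes), power
    eigen = module_eigengenes(filtered, partition)
    kme_table = kme(filtered, eigen)
    return filtered, partition, eigen, kme_table, power
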