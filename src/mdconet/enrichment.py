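"""Gene-set enrichment: running-sum GSEA and hypergeometric ORA.

Two complementary enrichment routes are provided:

* a rank-based running-sum enrichment score with a "gene set"
  permutation null (random same-size sets drawn from the ranked
  universe), the convention of the desktop GSEA tool;
* hypergeometric over-representation analysis (ORA) of a query gene
  list against a catalog, with Benjamini–Hochberg adjustment across the
  catalog.

``pathway_membership_counts`` supports the key-gene stage: for each
gene, the number of significant sets that contain it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCatalog, SampleLabels, ValidationError
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GseaResult",
    "rank_genes",
    "gsea_enrichment_score",
    "gsea_permutation_p",
    "ora_hypergeometric",
    "pathway_membership_counts",
]


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValidationError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list contains duplicate genes")
        if not np.all(np.isfinite(self.metric)):
            raise ValidationError("ranking metric must be finite")
        if np.any(np.diff(self.metric) > 0):
            raise ValidationError("metric must be ordered descending")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    metric: str = "signal_to_noise",
    sd_floor_fraction: float = 0.2,
) -> RankedList:
    """Rank genes by a two-group contrast metric, descending.

    ``signal_to_noise`` is ``(mu_A - mu_B) / (sd_A + sd_B)`` with each
    group standard deviation floored at ``sd_floor_fraction * |mu|`` (a
    positive metric means higher expression in condition A).
    ``t_statistic`` uses the Welch statistic.  Ties are broken by gene
    identifier so the order is deterministic.
    """
    mask_a, mask_b = labels.condition_masks(matrix)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValidationError("both groups need >= 3 samples for ranking")
    xa, xb = matrix.values[:, mask_a], matrix.values[:, mask_b]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    if metric == "signal_to_noise":
        sa = np.maximum(xa.std(axis=1, ddof=1), sd_floor_fraction * np.abs(ma))
        sb = np.maximum(xb.std(axis=1, ddof=1), sd_floor_fraction * np.abs(mb))
        denom = sa + sb
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)
    elif metric == "t_statistic":
        from .diffexpr import two_group_test

        de = two_group_test(matrix, labels)
        values = -de["stat"].to_numpy()  # positive = higher in A, as above
        values = np.where(np.isfinite(values), values, np.sign(values) * 1e12)
    else:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    order = sorted(
        range(matrix.n_genes), key=lambda i: (-values[i], matrix.genes[i])
    )
    return RankedList([matrix.genes[i] for i in order], values[np.array(order)])


def gsea_enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov–Smirnov-like running-sum enrichment score.

    Walking the ranked list, a hit increments the running sum by
    ``|metric|^weight / sum_hits |metric|^weight`` and a miss decrements
    it by ``1 / (N - N_hits)``; the enrichment score is the signed
    extremum.  Returns ``(ES, running_sum)``.
    """
    members = set(gene_set)
    hit = np.array([g in members for g in ranked.genes], dtype=bool)
    n_hits = int(hit.sum())
    n = len(ranked)
    if n_hits == 0:
        raise ValidationError("no gene-set member present in the ranked list")
    if n_hits == n:
        # every position is a hit; the sum climbs to exactly 1
        running = np.cumsum(np.abs(ranked.metric) ** weight)
        total = running[-1]
        running = running / total if total > 0 else np.linspace(1 / n, 1.0, n)
        return 1.0, running
    w = np.abs(ranked.metric) ** weight
    hit_mass = np.where(hit, w, 0.0)
    total = hit_mass.sum()
    if total == 0:  # all member metrics are zero; fall back to equal mass
        hit_mass = hit.astype(float)
        total = hit_mass.sum()
    running = np.cumsum(hit_mass / total - (~hit) / (n - n_hits))
    es = float(running[int(np.argmax(np.abs(running)))])
    return es, running


@dataclass
class GseaResult:
    """Permutation-based enrichment result for one gene set."""

    es: float
    nes: float
    pvalue: float
    n_perm: int
    set_size: int
    direction: str  # condition enriched at the top of the ranking

    def __post_init__(self) -> None:
        if not -1.0 <= self.es <= 1.0:
            raise ValidationError(f"enrichment score {self.es} outside [-1, 1]")


def gsea_permutation_p(
    ranked: RankedList,
    gene_set,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    direction_names: tuple[str, str] = ("A", "B"),
) -> GseaResult:
    """Gene-set permutation p-value for the running-sum score.

    The null is the ES of ``n_perm`` random same-size sets drawn from
    the ranked universe.  The empirical p is sign-stratified with a
    pseudocount — among the null scores of the observed sign,
    ``(1 + #{|ES_null| >= |ES_obs|}) / (1 + #same-sign nulls)`` — which
    keeps the p-value uniform under a random query set.  The normalised
    ES divides by the mean |ES| of same-sign null scores.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    members = [g for g in gene_set if g in set(ranked.genes)]
    size = len(set(members))
    if size == 0:
        raise ValidationError("no gene-set member present in the ranked list")
    if size >= len(ranked):
        raise ValidationError("gene set must be smaller than the ranked universe")
    es_obs, _ = gsea_enrichment_score(ranked, members, weight=weight)
    rng = np.random.default_rng(seed)
    genes = np.array(ranked.genes)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(genes, size=size, replace=False)
        null[i], _ = gsea_enrichment_score(ranked, draw, weight=weight)
    same_sign = null >= 0 if es_obs >= 0 else null < 0
    exceed = int(np.sum(same_sign & (np.abs(null) >= abs(es_obs))))
    pvalue = (1 + exceed) / (1 + int(same_sign.sum()))
    denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.abs(null).mean()
    nes = es_obs / denom if denom > 0 else 0.0
    return GseaResult(
        es=es_obs,
        nes=float(nes),
        pvalue=float(pvalue),
        n_perm=n_perm,
        set_size=size,
        direction=direction_names[0] if es_obs >= 0 else direction_names[1],
    )


def ora_hypergeometric(
    query, catalog: GeneSetCatalog, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each catalog set.

    For a set S the p-value is ``P[X >= k]`` with X hypergeometric on
    (N = |universe|, K = |S intersect universe|, n = |query|) and
    k = |query intersect S|.  Adjusted p-values are Benjamini–Hochberg
    across the catalog.  Returns a DataFrame indexed by set name with
    columns ``set_size``, ``overlap``, ``pvalue``, ``padj``.
    """
    query = set(query)
    universe = set(universe)
    if not universe or not query:
        raise ValidationError("query and universe must be non-empty")
    if not query <= universe:
        raise ValidationError(
            f"query genes outside universe: {sorted(query - universe)[:5]}"
        )
    n_univ, n_query = len(universe), len(query)
    rows = []
    for s in catalog:
        in_univ = set(s.members) & universe
        k = len(query & in_univ)
        if len(in_univ) == 0:
            pvalue = 1.0
        else:
            pvalue = float(stats.hypergeom.sf(k - 1, n_univ, len(in_univ), n_query))
        rows.append((s.name, len(in_univ), k, min(pvalue, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "pvalue"]
    ).set_index("set")
    frame["padj"] = bh_adjust(frame["pvalue"].to_numpy()) if len(frame) else []
    return frame


def pathway_membership_counts(
    genes, ora_result: pd.DataFrame, catalog: GeneSetCatalog, alpha: float = 0.05
) -> dict[str, int]:
    """Number of significant sets (adjusted p <= alpha) containing each gene."""
    significant = set(ora_result.index[ora_result["padj"] <= alpha])
    membership = {g: 0 for g in genes}
    for s in catalog:
        if s.name not in significant:
            continue
        for g in s.members:
            if g in membership:
                membership[g] += 1
    return membership
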