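"""Three-criterion key-gene prioritisation.

A candidate gene (member of the common up- or down-regulated lists) is
a key gene when it simultaneously

1. ranks in the top-N (default 20) by degree in the candidate-induced
   PPI subgraph,
2. ranks in the top-N by the number of significant pathways containing
   it, and
3. is a hub (|kME| above a threshold, default 0.85) of a module in
   which the candidate list is over-represented — in every supplied
   co-expression network.

Ranks are competition ranks ("1224"); the top-N cut includes every gene
tied at rank N, so results do not depend on arbitrary tie ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import ora_hypergeometric
from .io import GeneSet, GeneSetCatalog, PPIGraph, ValidationError
from .network import ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkEvidence",
    "KeyGeneReport",
    "ppi_degree_rank",
    "module_overrepresentation",
    "hub_genes",
    "select_key_genes",
]


def _competition_rank(values: np.ndarray) -> np.ndarray:
    """Competition rank of values, descending (largest value -> rank 1)."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(values.size, dtype=int)
    rank = 0
    prev = None
    for pos, i in enumerate(order, start=1):
        if prev is None or values[i] != prev:
            rank = pos
            prev = values[i]
        ranks[i] = rank
    return ranks


def ppi_degree_rank(
    graph: PPIGraph, candidates, top_n: int = 20
) -> pd.DataFrame:
    """Degree of each candidate in the candidate-induced subgraph.

    Candidates absent from the graph get degree 0.  Returns a DataFrame
    indexed by gene with columns ``degree``, ``rank`` and ``top``
    (competition rank <= top_n, ties included).
    """
    candidates = sorted(set(candidates))
    sub = graph.graph.subgraph([c for c in candidates if c in graph.graph])
    degree = np.array([sub.degree(c) if c in sub else 0 for c in candidates], dtype=int)
    ranks = _competition_rank(degree.astype(float))
    return pd.DataFrame(
        {"degree": degree, "rank": ranks, "top": ranks <= top_n},
        index=pd.Index(candidates, name="gene"),
    )


def pathway_count_rank(counts: dict[str, int], top_n: int = 20) -> pd.DataFrame:
    """Competition-rank per-gene pathway membership counts."""
    genes = sorted(counts)
    values = np.array([counts[g] for g in genes], dtype=float)
    ranks = _competition_rank(values)
    return pd.DataFrame(
        {"pathway_count": values.astype(int), "rank": ranks, "top": ranks <= top_n},
        index=pd.Index(genes, name="gene"),
    )


def module_overrepresentation(
    candidates, partition: ModulePartition, universe, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation of candidates in each module.

    Benjamini–Hochberg across modules; a module is enriched when its
    adjusted p <= alpha.  Returns a DataFrame indexed by ``module``
    (names ``M<label>``) with ``set_size``, ``overlap``, ``pvalue``,
    ``padj``, ``enriched``.
    """
    candidates = set(candidates)
    universe = set(universe)
    if not candidates <= universe:
        raise ValidationError("candidates must be a subset of the universe")
    sets = [
        GeneSet(f"M{m}", f"module {m}", tuple(partition.members(m)))
        for m in range(1, partition.n_modules + 1)
    ]
    if not sets:
        return pd.DataFrame(
            columns=["set_size", "overlap", "pvalue", "padj", "enriched"]
        )
    result = ora_hypergeometric(candidates, GeneSetCatalog(sets), universe)
    result["enriched"] = result["padj"] <= alpha
    result.index.name = "module"
    return result


@dataclass
class NetworkEvidence:
    """One co-expression network's contribution to the hub criterion."""

    partition: ModulePartition
    kme_table: pd.DataFrame
    enriched_modules: set[int]


def hub_genes(
    evidence: NetworkEvidence, candidates, kme_threshold: float = 0.85
) -> set[str]:
    """Candidates that are hubs of an enriched module in one network.

    A gene qualifies when its assigned module is enriched and its |kME|
    with that module's eigengene exceeds ``kme_threshold``.
    """
    module_of = evidence.partition.module_of()
    out = set()
    for g in candidates:
        m = module_of.get(g, 0)
        if m == 0 or m not in evidence.enriched_modules:
            continue
        col = f"ME{m}"
        if col in evidence.kme_table.columns and g in evidence.kme_table.index:
            if abs(float(evidence.kme_table.loc[g, col])) > kme_threshold:
                out.add(g)
    return out


@dataclass
class KeyGeneReport:
    """Per-candidate criterion table and the final key-gene set."""

    table: pd.DataFrame
    key_genes: set[str] = field(default_factory=set)


def select_key_genes(
    degree_table: pd.DataFrame,
    pathway_counts: dict[str, int],
    networks: list[NetworkEvidence],
    top_n: int = 20,
    kme_threshold: float = 0.85,
) -> KeyGeneReport:
    """Intersect the three key-gene criteria over one candidate list.

    ``degree_table`` is the output of :func:`ppi_degree_rank`;
    ``pathway_counts`` maps each candidate to its significant-pathway
    count; ``networks`` supplies one or more co-expression networks,
    and the hub criterion must hold in every one of them.
    """
    candidates = sorted(degree_table.index)
    if sorted(pathway_counts) != candidates:
        raise ValidationError("degree and pathway inputs cover different candidates")
    if not networks:
        raise ValidationError("at least one network is required")
    path_table = pathway_count_rank(pathway_counts, top_n=top_n)
    deg_ranked = ppi_degree_rank_from_table(degree_table, top_n)
    hub_sets = [hub_genes(ev, candidates, kme_threshold) for ev in networks]
    hubs_all = set.intersection(*hub_sets)

    table = pd.DataFrame(index=pd.Index(candidates, name="gene"))
    table["degree"] = deg_ranked["degree"]
    table["degree_rank"] = deg_ranked["rank"]
    table["top_degree"] = deg_ranked["top"]
    table["pathway_count"] = path_table["pathway_count"]
    table["pathway_rank"] = path_table["rank"]
    table["top_pathways"] = path_table["top"]
    table["hub"] = [g in hubs_all for g in candidates]
    for n, ev in enumerate(networks):
        module_of = ev.partition.module_of()
        best = []
        for g in candidates:
            m = module_of.get(g, 0)
            col = f"ME{m}"
            if m and col in ev.kme_table.columns and g in ev.kme_table.index:
                best.append(float(ev.kme_table.loc[g, col]))
            else:
                best.append(np.nan)
        table[f"kme_net{n + 1}"] = best
    table["key"] = table["top_degree"] & table["top_pathways"] & table["hub"]
    keys = set(table.index[table["key"]])
    if not keys:
        logger.warning("no gene satisfies all three key-gene criteria")
    return KeyGeneReport(table, keys)


def ppi_degree_rank_from_table(degree_table: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Re-rank a degree table at a possibly different top-N cut."""
    degree = degree_table["degree"].to_numpy(dtype=float)
    ranks = _competition_rank(degree)
    out = degree_table.copy()
    out["rank"] = ranks
    out["top"] = ranks <= top_n
    return out
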