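"""Synthetic two-condition cohort generator with planted network structure.

The generator emulates the statistical skeleton of a paired microarray
study of a progressive disease: two cohorts measured on the same genes,
each split into two conditions (A = less advanced, B = more advanced),
with

* planted co-expression modules following a single-factor Gaussian
  model — gene ``g`` in module ``m`` observes
  ``x_g = sd * (lambda_g * z_m + sqrt(1 - lambda_g^2) * eps_g)``
  with independent standard-normal factor ``z_m`` and noise ``eps_g``,
  so the expected pairwise correlation of two ordinary members is
  ``rho = lambda^2``; the per-condition ``rho`` is configurable, which
  plants modular differential connectivity;
* planted differentially expressed (DE) genes: an additive shift on the
  log2 scale in condition B, shared across cohorts or cohort-specific
  (``fold change > 2`` corresponds to ``|shift| > 1``);
* designated key genes: module members with an elevated factor loading
  (high module membership), a strong DE shift, a boosted degree in the
  companion PPI graph, and guaranteed membership in several gene sets.

Everything is driven by one integer seed and is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, GeneSet, GeneSetCatalog, PPIGraph, SampleLabels

logger = logging.getLogger(__name__)

__all__ = [
    "DEGene",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "simulate_cohort",
    "simulate_paired_cohorts",
    "simulate_ppi",
    "simulate_gene_sets",
]


class ConfigurationError(ValueError):
    """A simulation configuration violated an invariant."""


@dataclass(frozen=True)
class DEGene:
    """A planted differentially expressed gene.

    ``log2fc`` is added to condition-B samples.  ``shared`` genes are
    shifted in every cohort; otherwise only in cohort ``cohort``.
    """

    gene: str
    log2fc: float
    shared: bool = True
    cohort: int | None = None


@dataclass
class SimulationConfig:
    """Parameters of the paired-cohort simulation.

    ``module_rho`` gives, per module, the expected within-module pairwise
    correlation in condition A and condition B; genes beyond
    ``sum(module_sizes)`` are independent background noise.  Key genes
    get factor loading ``key_gene_loading`` (instead of ``sqrt(rho)``),
    i.e. deliberately high module membership.

    ``module_factor_shift`` moves a module's latent factor by ``d`` in
    condition B, so every member inherits an additive log2 shift of
    ``loading * d`` — the way a disease-axis module behaves in real
    cohorts, where the module eigengene itself separates the
    conditions.  Members of a shifted module are therefore planted DE
    genes (shared across cohorts) without a per-gene entry in
    ``de_genes``.
    """

    n_genes: int = 1200
    module_sizes: Sequence[int] = (100, 100, 80, 80, 60)
    module_rho: Sequence[tuple[float, float]] = (
        (0.25, 0.25),
        (0.25, 0.25),
        (0.6, 0.2),
        (0.2, 0.6),
        (0.4, 0.4),
    )
    module_factor_shift: Sequence[float] = (2.2, -2.2, 0.0, 0.0, 0.0)
    samples_per_condition: Sequence[tuple[int, int]] = ((32, 32), (13, 16))
    de_genes: Sequence[DEGene] = ()
    key_genes: Sequence[str] = ()
    key_gene_loading: float = 0.95
    noise_sd: float = 1.0
    seed: int = 0

    @property
    def n_cohorts(self) -> int:
        return len(self.samples_per_condition)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def module_of(self) -> dict[str, int]:
        """Map gene -> module label (1-based; 0 = background)."""
        out: dict[str, int] = {}
        genes = self.gene_ids
        pos = 0
        for m, size in enumerate(self.module_sizes, start=1):
            for g in genes[pos : pos + size]:
                out[g] = m
            pos += size
        for g in genes[pos:]:
            out[g] = 0
        return out

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if len(self.module_rho) != len(self.module_sizes):
            raise ConfigurationError("module_rho and module_sizes length mismatch")
        if len(self.module_factor_shift) != len(self.module_sizes):
            raise ConfigurationError(
                "module_factor_shift and module_sizes length mismatch"
            )
        for m, (ra, rb) in enumerate(self.module_rho, start=1):
            for r in (ra, rb):
                if not 0.0 <= r < 1.0:
                    raise ConfigurationError(
                        f"module {m}: rho must be in [0, 1), got {r}"
                    )
        if not 0.0 < self.key_gene_loading < 1.0:
            raise ConfigurationError("key_gene_loading must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        genes = set(self.gene_ids)
        module_of = self.module_of()
        for d in self.de_genes:
            if d.gene not in genes:
                raise ConfigurationError(f"DE gene {d.gene!r} outside the gene list")
            if not d.shared and not (
                d.cohort is not None and 0 <= d.cohort < self.n_cohorts
            ):
                raise ConfigurationError(
                    f"cohort-specific DE gene {d.gene!r} needs a valid cohort index"
                )
        for g in self.key_genes:
            if g not in genes:
                raise ConfigurationError(f"key gene {g!r} outside the gene list")
            if module_of[g] == 0:
                raise ConfigurationError(f"key gene {g!r} must belong to a module")
        for nA, nB in self.samples_per_condition:
            if nA < 3 or nB < 3:
                raise ConfigurationError("each condition needs at least 3 samples")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated pair of cohorts."""

    gene_ids: list[str]
    module_of: dict[str, int]
    module_rho: list[tuple[float, float]]
    module_factor_shift: list[float]
    de_genes: list[DEGene]
    key_genes: list[str]
    seed: int

    def de_for_cohort(self, cohort: int) -> dict[str, float]:
        return {
            d.gene: d.log2fc
            for d in self.de_genes
            if d.shared or d.cohort == cohort
        }

    def shared_de(self, direction: str | None = None) -> set[str]:
        """Shared planted DE genes; ``direction`` in {'up', 'down', None}."""
        out = set()
        for d in self.de_genes:
            if not d.shared:
                continue
            if direction == "up" and d.log2fc <= 0:
                continue
            if direction == "down" and d.log2fc >= 0:
                continue
            out.add(d.gene)
        return out

    def all_de(self) -> set[str]:
        return {d.gene for d in self.de_genes}

    def module_labels(self) -> np.ndarray:
        return np.array([self.module_of[g] for g in self.gene_ids], dtype=int)


def default_config(seed: int = 0) -> SimulationConfig:
    """The default planted scenario.

    Two cohorts sized like a typical pair of plaque-stage microarray
    series (32 vs 32 and 13 vs 16 samples).  Five modules of 100, 100,
    80, 80 and 60 genes; modules 3 and 4 lose/gain within-module
    correlation strongly between conditions (0.6 vs 0.2), module 5 is a
    connectivity-null module.  Modules 1 and 2 are disease-axis
    modules: their factors shift by +2.2 / -2.2 in condition B, so
    ordinary members (loading 0.5) inherit a +/-1.1 log2 shift and the
    eight key genes — four per disease module, loading 0.95 — inherit
    +/-2.1.  A
    further 30 background genes per direction are shared DE genes at
    +/-1.5, and each cohort gets 25 private DE genes per direction.
    """
    cfg = SimulationConfig(seed=seed)
    genes = cfg.gene_ids
    sizes = list(cfg.module_sizes)
    m1 = genes[0 : sizes[0]]
    m2 = genes[sizes[0] : sizes[0] + sizes[1]]
    background = genes[sum(sizes) :]

    key_up = m1[:4]
    key_down = m2[:4]
    de: list[DEGene] = []
    de += [DEGene(g, +1.5) for g in background[0:30]]
    de += [DEGene(g, -1.5) for g in background[30:60]]
    # cohort-private DE genes, disjoint blocks of background
    de += [DEGene(g, +1.5, shared=False, cohort=0) for g in background[60:85]]
    de += [DEGene(g, -1.5, shared=False, cohort=0) for g in background[85:110]]
    de += [DEGene(g, +1.5, shared=False, cohort=1) for g in background[110:135]]
    de += [DEGene(g, -1.5, shared=False, cohort=1) for g in background[135:160]]

    cfg.de_genes = tuple(de)
    cfg.key_genes = tuple(key_up + key_down)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------


def _loadings(config: SimulationConfig, rho_index: int) -> np.ndarray:
    """Per-gene factor loading for one condition (column of module_rho)."""
    lam = np.zeros(config.n_genes)
    module_of = config.module_of()
    keys = set(config.key_genes)
    for i, g in enumerate(config.gene_ids):
        m = module_of[g]
        if m == 0:
            continue
        lam[i] = (
            config.key_gene_loading
            if g in keys
            else np.sqrt(config.module_rho[m - 1][rho_index])
        )
    return lam


def _cohort_seed(seed: int, cohort: int) -> int:
    return (seed * 1_000_003 + 7919 * (cohort + 1)) % 2**31


def simulate_cohort(
    config: SimulationConfig, cohort: int = 0
) -> tuple[ExpressionMatrix, SampleLabels]:
    """Simulate one cohort (both conditions) of the configured design.

    Returns the genes x samples matrix and the sample condition labels.
    Condition-B samples carry the planted DE shifts applicable to this
    cohort.  Deterministic given ``config.seed`` and ``cohort``.
    """
    config.validate()
    if not 0 <= cohort < config.n_cohorts:
        raise ConfigurationError(f"cohort index {cohort} out of range")
    rng = np.random.default_rng(_cohort_seed(config.seed, cohort))
    nA, nB = config.samples_per_condition[cohort]
    genes = config.gene_ids
    module_labels = np.array([config.module_of()[g] for g in genes])
    de = {}
    for d in config.de_genes:
        if d.shared or d.cohort == cohort:
            de[d.gene] = d.log2fc
    shifts = np.array([de.get(g, 0.0) for g in genes])

    blocks = []
    for cond, n in (("A", nA), ("B", nB)):
        lam = _loadings(config, 0 if cond == "A" else 1)
        z = rng.standard_normal((len(config.module_sizes) + 1, n))  # row 0 unused
        if cond == "B":
            # disease-axis modules: the factor itself moves in condition B
            z[1:] += np.asarray(config.module_factor_shift, dtype=float)[:, None]
        eps = rng.standard_normal((config.n_genes, n))
        x = lam[:, None] * z[module_labels] + np.sqrt(1 - lam**2)[:, None] * eps
        x *= config.noise_sd
        if cond == "B":
            x += shifts[:, None]
        blocks.append(x)

    values = np.hstack(blocks)
    samples = [f"C{cohort + 1}A{j:02d}" for j in range(nA)] + [
        f"C{cohort + 1}B{j:02d}" for j in range(nB)
    ]
    mapping = {s: ("A" if j < nA else "B") for j, s in enumerate(samples)}
    return ExpressionMatrix(genes, samples, values), SampleLabels(mapping)


def simulate_paired_cohorts(
    config: SimulationConfig,
) -> tuple[list[tuple[ExpressionMatrix, SampleLabels]], SyntheticTruth]:
    """Simulate every configured cohort plus the ground-truth record."""
    config.validate()
    cohorts = [simulate_cohort(config, c) for c in range(config.n_cohorts)]
    # members of factor-shifted modules are DE by construction; record
    # their effective log2 shift (loading_B * d * noise_sd) in the truth
    derived: list[DEGene] = []
    module_of = config.module_of()
    keys = set(config.key_genes)
    for g in config.gene_ids:
        m = module_of[g]
        if m == 0:
            continue
        d = config.module_factor_shift[m - 1]
        if d == 0:
            continue
        lam_b = (
            config.key_gene_loading if g in keys else np.sqrt(config.module_rho[m - 1][1])
        )
        derived.append(DEGene(g, float(lam_b * d * config.noise_sd)))
    truth = SyntheticTruth(
        gene_ids=config.gene_ids,
        module_of=module_of,
        module_rho=list(config.module_rho),
        module_factor_shift=list(config.module_factor_shift),
        de_genes=list(config.de_genes) + derived,
        key_genes=list(config.key_genes),
        seed=config.seed,
    )
    return cohorts, truth


def simulate_ppi(
    truth: SyntheticTruth,
    background_edge_prob: float = 0.02,
    key_gene_degree_boost: int = 30,
    seed: int | None = None,
) -> PPIGraph:
    """Simulate a PPI graph whose degree concentrates on the key genes.

    Each designated key gene is wired to ``key_gene_degree_boost``
    distinct partners drawn from the shared DE genes of its own
    regulation direction (so the boost survives restriction to a
    candidate-induced subgraph); all other pairs follow an
    Erdos–Renyi background with probability ``background_edge_prob``.
    """
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ConfigurationError("background_edge_prob must be in [0, 1]")
    if key_gene_degree_boost < 0:
        raise ConfigurationError("key_gene_degree_boost must be >= 0")
    rng = np.random.default_rng(truth.seed + 17 if seed is None else seed)
    genes = truth.gene_ids
    n = len(genes)
    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    de_sign = {d.gene: d.log2fc for d in truth.de_genes if d.shared}
    for key in truth.key_genes:
        direction = "up" if de_sign.get(key, 1.0) > 0 else "down"
        pool = sorted(truth.shared_de(direction) - {key})
        if not pool and key_gene_degree_boost > 0:
            raise ConfigurationError(
                f"no shared DE partners available for key gene {key!r}"
            )
        n_pick = min(key_gene_degree_boost, len(pool))
        for partner in rng.choice(pool, size=n_pick, replace=False):
            add(key, str(partner))

    if background_edge_prob > 0:
        n_pairs = n * (n - 1) // 2
        m = rng.binomial(n_pairs, background_edge_prob)
        # sample m unordered pairs (with replacement, then dedup against
        # existing edges; for small p the collision loss is negligible)
        i = rng.integers(0, n, size=2 * m)
        j = rng.integers(0, n, size=2 * m)
        added = 0
        for a, b in zip(i, j):
            if a == b:
                continue
            before = len(edges)
            add(genes[a], genes[b])
            added += len(edges) - before
            if added >= m:
                break
    graph = PPIGraph.from_edges(edges)
    graph.graph.add_nodes_from(genes)
    return graph


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_random_sets: int = 40,
    sets_per_key_gene: int = 12,
    set_size: int = 12,
    overlap_noise: float = 0.5,
    seed: int | None = None,
) -> GeneSetCatalog:
    """Simulate a gene-set catalog aligned with the planted DE structure.

    For every key gene, ``sets_per_key_gene`` sets contain it; the other
    members of such a planted set are drawn from the shared DE genes of
    the key gene's direction (fraction ``1 - overlap_noise``) and from
    the remaining genes (fraction ``overlap_noise``), so planted sets
    are recoverable by over-representation of the common DE list while
    key genes attain the top per-gene membership counts.  A further
    ``n_random_sets`` sets are uniform draws.
    """
    if not 0.0 <= overlap_noise <= 1.0:
        raise ConfigurationError("overlap_noise must be in [0, 1]")
    if set_size < 2:
        raise ConfigurationError("set_size must be >= 2")
    rng = np.random.default_rng(truth.seed + 29 if seed is None else seed)
    genes = np.array(truth.gene_ids)
    de_sign = {d.gene: d.log2fc for d in truth.de_genes if d.shared}
    sets: list[GeneSet] = []
    n_fillers = set_size - 1
    n_de_fillers = int(round(n_fillers * (1.0 - overlap_noise)))
    for key in truth.key_genes:
        direction = "up" if de_sign.get(key, 1.0) > 0 else "down"
        de_pool = sorted(truth.shared_de(direction) - set(truth.key_genes))
        other_pool = sorted(set(truth.gene_ids) - set(de_pool) - {key})
        for i in range(sets_per_key_gene):
            members = [key]
            members += list(
                rng.choice(de_pool, size=min(n_de_fillers, len(de_pool)), replace=False)
            )
            members += list(
                rng.choice(other_pool, size=n_fillers - (len(members) - 1), replace=False)
            )
            sets.append(
                GeneSet(
                    f"PLANTED_{key}_{i:02d}",
                    f"planted set around {key}",
                    tuple(str(m) for m in members),
                )
            )
    for i in range(n_random_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets.append(
            GeneSet(f"RANDOM_{i:03d}", "random set", tuple(str(m) for m in members))
        )
    return GeneSetCatalog(sets, namespace="GOBP-like")
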