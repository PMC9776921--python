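"""Plain-text readers and writers for the pipeline's four data types.

Every format is tab-separated text:

* expression — genes in rows, samples in columns, first row/column are
  identifiers, values are continuous (log2 intensities or log2(count+1));
* sample labels — two columns ``sample_id<TAB>condition``;
* gene sets — GMT (``name<TAB>description<TAB>member...``);
* protein–protein interactions — two or three columns
  ``node<TAB>node[<TAB>score]``.

Validation fails loudly: duplicate identifiers, non-numeric or missing
expression values, and malformed lines raise instead of being silently
repaired.  Gene identifiers are opaque, case-sensitive strings; no
probe-to-symbol mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleLabels",
    "GeneSet",
    "GeneSetCatalog",
    "PPIGraph",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
]


class ValidationError(ValueError):
    """An input violated a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries coordinates."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric table.

    Invariants: unique gene and sample identifiers, all values finite,
    at least 2 genes and 4 samples.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.genes) < 2 or len(self.samples) < 4:
            raise ValidationError(
                "expression matrix needs at least 2 genes and 4 samples, got "
                f"{len(self.genes)} x {len(self.samples)}"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.genes[g]!r}, sample {self.samples[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([pos[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown gene {exc.args[0]!r}") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.samples), self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in samples], dtype=int)
        return ExpressionMatrix(list(self.genes), list(samples), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class SampleLabels:
    """Two-condition sample labelling.

    ``mapping`` assigns each sample to condition ``"A"`` or ``"B"``;
    ``display_names`` carries human-readable condition names (for example
    ``{"A": "early", "B": "advanced"}``).
    """

    mapping: dict[str, str]
    display_names: dict[str, str] = field(
        default_factory=lambda: {"A": "A", "B": "B"}
    )

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in ("A", "B")}
        if bad:
            raise ValidationError(f"conditions must be 'A' or 'B', got {sorted(bad)}")
        for cond in ("A", "B"):
            if len(self.samples_in(cond)) < 3:
                raise ValidationError(
                    f"condition {cond!r} has fewer than 3 samples"
                )

    def samples_in(self, condition: str) -> list[str]:
        return [s for s, c in self.mapping.items() if c == condition]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check labels and matrix refer to the same samples."""
        missing = [s for s in self.mapping if s not in set(matrix.samples)]
        if missing:
            raise ValidationError(f"labelled samples not in matrix: {missing}")
        unlabelled = [s for s in matrix.samples if s not in self.mapping]
        if unlabelled:
            raise ValidationError(f"matrix samples without a label: {unlabelled}")

    def condition_masks(self, matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks over ``matrix.samples`` for conditions A and B."""
        self.validate_against(matrix)
        conds = np.array([self.mapping[s] for s in matrix.samples])
        return conds == "A", conds == "B"


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        # collapse duplicates, keep first-seen order
        seen: dict[str, None] = dict.fromkeys(self.members)
        self.members = tuple(seen)
        if len(self.members) < 1:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCatalog:
    """An ordered collection of named gene sets (one GMT file)."""

    sets: list[GeneSet]
    namespace: str = ""

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def sets_containing(self, gene: str) -> list[str]:
        return [s.name for s in self.sets if gene in s.members]


@dataclass
class PPIGraph:
    """Undirected protein–protein interaction graph (no self-loops)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops present: {loops[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "PPIGraph":
        """Build a graph from an edge iterable.

        Reversed duplicates are merged and self-loops dropped (with a
        logged count), so the result stores each unordered pair once.
        """
        g = nx.Graph()
        n_loops = 0
        for edge in edges:
            u, v = str(edge[0]), str(edge[1])
            if u == v:
                n_loops += 1
                continue
            if len(edge) > 2:
                g.add_edge(u, v, score=float(edge[2]))
            else:
                g.add_edge(u, v)
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        return cls(g)

    def degree(self, node: str) -> int:
        return int(self.graph.degree(node)) if node in self.graph else 0

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated genes x samples table.

    The first row holds sample identifiers, the first column gene
    identifiers.  Missing-value tokens such as ``NA`` are rejected rather
    than imputed.
    """
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    genes = [str(g) for g in frame.index]
    samples = [str(s) for s in frame.columns]
    _check_unique(genes, "gene")
    _check_unique(samples, "sample")
    raw = frame.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {raw[i, j]!r} at gene {genes[i]!r} "
                    f"(row {i + 2}), sample {samples[j]!r} (column {j + 2})"
                ) from None
    return ExpressionMatrix(genes, samples, values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="gene")


# ---------------------------------------------------------------------------
# labels


def read_labels(
    path: str | Path, display_names: Mapping[str, str] | None = None
) -> SampleLabels:
    """Read a two-column ``sample<TAB>condition`` file (conditions A/B)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            sample, cond = parts
            if sample in mapping:
                raise ValidationError(f"duplicate sample identifier: {sample!r}")
            mapping[sample] = cond
    return SampleLabels(mapping, dict(display_names) if display_names else {"A": "A", "B": "B"})


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, cond in labels.mapping.items():
            fh.write(f"{sample}\t{cond}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, namespace: str = "") -> GeneSetCatalog:
    """Read a GMT gene-set file (one set per line).

    Duplicate members within a line are collapsed.  An empty file yields
    an empty catalog with a warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT lines need at least 3 fields "
                    f"(name, description, member...), got {len(parts)}"
                )
            sets.append(GeneSet(parts[0], parts[1], tuple(parts[2:])))
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCatalog(sets, namespace=namespace)


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in catalog:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# edge list


def read_edge_list(path: str | Path) -> PPIGraph:
    """Read a 2- or 3-column tab-separated edge list into an undirected graph."""
    edges: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) == 3:
                try:
                    score = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric score {parts[2]!r}"
                    ) from None
                edges.append((parts[0], parts[1], score))
            else:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 or 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
    return PPIGraph.from_edges(edges)


def write_edge_list(ppi: PPIGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(ppi.graph.edges(data=True)):
            if "score" in data:
                fh.write(f"{u}\t{v}\t{data['score']:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")
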