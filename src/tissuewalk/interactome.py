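"""Interactome assembly and tissue-specific Markov transition matrices.

Edge lists from several interaction databases are merged into one undirected,
deduplicated network. Each edge is then weighted for a given tissue or
cell-type by two biophysical proxies:

* subcellular co-localization — the Jaccard similarity of the two proteins'
  micro-domain annotation sets, floored at a small positive value so that the
  walk never disconnects along an annotated edge;
* protein abundance — the geometric mean of the two proteins' ordinal
  abundance levels in that tissue, mapped to positive numbers.

Row-normalizing the weighted adjacency yields a row-stochastic transition
matrix P per tissue: P[u, v] is the probability that disease signal at gene u
moves to neighbor v in one diffusion step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ORDINAL_LEVELS",
    "DEFAULT_ABUNDANCE_MAPPING",
    "DEFAULT_FLOOR",
    "AnnotationError",
    "InteractionSet",
    "LocalizationMap",
    "AbundanceMatrix",
    "TissueTransitionMatrix",
    "merge_and_dedupe",
    "localization_weight",
    "abundance_factor",
    "build_transition_matrix",
    "build_all_tissues",
]

#: the four ordinal protein-abundance levels, lowest to highest
ORDINAL_LEVELS = ("not_detected", "low", "medium", "high")

#: default map from ordinal level to a positive weight; "not_detected" stays
#: strictly positive so annotated edges never fully disconnect a node
DEFAULT_ABUNDANCE_MAPPING: dict[str, float] = {
    "not_detected": 0.1,
    "low": 1.0,
    "medium": 2.0,
    "high": 3.0,
}

#: default positive floor for the co-localization weight
DEFAULT_FLOOR = 0.01


class AnnotationError(ValueError):
    """An interacting gene is missing localization or abundance annotation."""


@dataclass(frozen=True)
class InteractionSet:
    """Canonicalized undirected gene-gene edges with source provenance.

    Each unordered pair appears exactly once, stored lexicographically
    ordered; self-pairs are excluded at construction time by
    :func:`merge_and_dedupe`.
    """

    edges: tuple[tuple[str, str], ...]
    sources: Mapping[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair {a!r} not allowed")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"edge ({a!r}, {b!r}) not canonically ordered")
            if (a, b) in seen:
                raise ValueError(f"duplicate edge ({a!r}, {b!r})")
            seen.add((a, b))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, ";".join(sorted(self.sources.get((a, b), frozenset()))))
            for a, b in self.edges
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "sources"])


@dataclass(frozen=True)
class LocalizationMap:
    """Per-gene micro-domain annotation over a fixed domain vocabulary."""

    domains: Mapping[str, frozenset[str]]
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        for gene, doms in self.domains.items():
            if not doms:
                raise AnnotationError(f"gene {gene!r} has no micro-domain label")
            if not set(doms) <= vocab:
                raise AnnotationError(
                    f"gene {gene!r} uses domains outside the vocabulary: "
                    f"{sorted(set(doms) - vocab)}"
                )

    def __contains__(self, gene: str) -> bool:
        return gene in self.domains

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.domains[gene]


@dataclass(frozen=True)
class AbundanceMatrix:
    """Gene x tissue/cell-type ordinal abundance levels."""

    levels: pd.DataFrame  # values are strings from ORDINAL_LEVELS

    def __post_init__(self) -> None:
        if self.levels.columns.duplicated().any():
            raise ValueError("tissue labels must be unique")
        bad = ~self.levels.isin(ORDINAL_LEVELS)
        if bad.to_numpy().any():
            cell = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"invalid abundance level {self.levels.iat[cell[0], cell[1]]!r} "
                f"for gene {self.levels.index[cell[0]]!r}"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.levels.index)

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.levels.columns)

    def level(self, gene: str, tissue: str) -> str:
        return self.levels.at[gene, tissue]


@dataclass(frozen=True)
class TissueTransitionMatrix:
    """Row-stochastic gene x gene transition matrix for one tissue."""

    tissue: str
    genes: tuple[str, ...]
    matrix: sparse.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix dimension does not match the gene index")
        if (self.matrix.data < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            worst = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ValueError(
                f"row {self.genes[worst]!r} sums to {rowsum[worst]:.12f}, not 1"
            )

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), index=list(self.genes),
                            columns=list(self.genes))


def _iter_raw_edges(source) -> Iterable[tuple[str, str, str]]:
    if isinstance(source, pd.DataFrame):
        for a, b, *rest in source.itertuples(index=False):
            yield str(a), str(b), str(rest[0]) if rest else ""
    else:
        for rec in source:
            a, b = rec[0], rec[1]
            yield str(a), str(b), str(rec[2]) if len(rec) > 2 else ""


def merge_and_dedupe(
    sources: Sequence,
    universe: Sequence[str] | None = None,
) -> InteractionSet:
    """Merge raw multi-source edge lists into one canonical undirected set.

    Pairs are canonicalized to lexicographic order, self-interactions are
    dropped, and duplicates (within or across sources, in either orientation)
    collapse to a single edge whose provenance is the union of source labels.

    Parameters
    ----------
    sources
        Edge lists: DataFrames with columns (gene_a, gene_b, source) or
        iterables of (gene_a, gene_b[, source]) records.
    universe
        Optional known gene symbols; an edge naming an unknown gene raises
        a ``ValueError`` naming that gene.
    """
    if len(sources) == 0:
        raise ValueError("at least one interaction source is required")
    known = set(universe) if universe is not None else None
    provenance: dict[tuple[str, str], set[str]] = {}
    n_self = n_raw = 0
    for k, source in enumerate(sources):
        for a, b, label in _iter_raw_edges(source):
            n_raw += 1
            if known is not None:
                for g in (a, b):
                    if g not in known:
                        raise ValueError(f"edge references unknown gene {g!r}")
            if a == b:
                n_self += 1
                continue
            pair = (a, b) if a < b else (b, a)
            provenance.setdefault(pair, set()).add(label or f"source_{k + 1}")
    edges = tuple(sorted(provenance))
    logger.info("merged %d raw records into %d unique interactions "
                "(%d self-pairs dropped)", n_raw, len(edges), n_self)
    return InteractionSet(
        edges=edges,
        sources={e: frozenset(provenance[e]) for e in edges},
    )


def localization_weight(
    domains_a: frozenset[str] | set[str],
    domains_b: frozenset[str] | set[str],
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Co-localization weight: Jaccard similarity of micro-domain sets, floored.

    Proteins sharing micro-domains are more likely to interact, so their edge
    carries more of the walk; the positive floor keeps every annotated edge
    traversable.
    """
    if not domains_a or not domains_b:
        raise AnnotationError("localization missing: empty micro-domain set")
    if not 0.0 < floor <= 1.0:
        raise ValueError(f"floor must be in (0, 1], got {floor}")
    a, b = set(domains_a), set(domains_b)
    jac = len(a & b) / len(a | b)
    return max(jac, floor)


def abundance_factor(
    level_a: str,
    level_b: str,
    mapping: Mapping[str, float] = DEFAULT_ABUNDANCE_MAPPING,
) -> float:
    """Pairwise abundance factor: geometric mean of the mapped ordinal levels."""
    for lev in (level_a, level_b):
        if lev not in mapping:
            raise ValueError(f"unmapped abundance level {lev!r}")
        if mapping[lev] <= 0:
            raise ValueError(f"mapped value for {lev!r} must be positive")
    return math.sqrt(mapping[level_a] * mapping[level_b])


def _edge_weights(
    interactions: InteractionSet,
    loc: LocalizationMap,
    abund: AbundanceMatrix,
    tissue: str,
    floor: float,
    mapping: Mapping[str, float],
    permissive: bool,
) -> tuple[list[tuple[int, int]], list[float], tuple[str, ...]]:
    genes = abund.genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    level_col = abund.levels[tissue]

    def annot(gene: str) -> tuple[frozenset[str], str]:
        missing = []
        doms = loc.domains.get(gene)
        if doms is None:
            missing.append("localization")
        lev = level_col.get(gene)
        if lev is None:
            missing.append("abundance")
        if missing:
            if not permissive:
                raise AnnotationError(
                    f"gene {gene!r} lacks {' and '.join(missing)} annotation"
                )
            logger.warning("permissive mode: defaulting %s for gene %s",
                           "+".join(missing), gene)
            doms = doms if doms is not None else frozenset(("__unannotated__",))
            lev = lev if lev is not None else "low"
        return doms, lev

    pairs: list[tuple[int, int]] = []
    weights: list[float] = []
    for a, b in interactions.edges:
        if a not in gene_idx or b not in gene_idx:
            missing = a if a not in gene_idx else b
            raise AnnotationError(f"gene {missing!r} lacks abundance annotation")
        (da, la), (db, lb) = annot(a), annot(b)
        if "__unannotated__" in da or "__unannotated__" in db:
            w_loc = floor
        else:
            w_loc = localization_weight(da, db, floor)
        w = w_loc * abundance_factor(la, lb, mapping)
        pairs.append((gene_idx[a], gene_idx[b]))
        weights.append(w)
    return pairs, weights, genes


def build_transition_matrix(
    interactions: InteractionSet,
    loc: LocalizationMap,
    abund: AbundanceMatrix,
    tissue: str,
    floor: float = DEFAULT_FLOOR,
    mapping: Mapping[str, float] = DEFAULT_ABUNDANCE_MAPPING,
    permissive: bool = False,
) -> TissueTransitionMatrix:
    """Row-stochastic transition matrix for one tissue.

    Raw symmetric edge weight: W[u, v] = localization_weight(u, v) *
    abundance_factor(u, v | tissue). Genes with no weighted edge (isolated in
    the network) get a unit self-loop so P stays stochastic; rows are then
    normalized to sum to one.
    """
    if tissue not in abund.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    pairs, weights, genes = _edge_weights(
        interactions, loc, abund, tissue, floor, mapping, permissive
    )
    n = len(genes)
    if pairs:
        rows = np.array([p[0] for p in pairs] + [p[1] for p in pairs])
        cols = np.array([p[1] for p in pairs] + [p[0] for p in pairs])
        vals = np.array(weights + weights, dtype=float)
    else:
        rows = cols = np.array([], dtype=int)
        vals = np.array([], dtype=float)
    w = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    rowsum = np.asarray(w.sum(axis=1)).ravel()
    isolated = np.flatnonzero(rowsum == 0.0)
    if isolated.size:
        loop = sparse.coo_matrix(
            (np.ones(isolated.size), (isolated, isolated)), shape=(n, n)
        )
        w = (w + loop).tocsr()
        rowsum[isolated] = 1.0
    p = sparse.diags(1.0 / rowsum) @ w
    return TissueTransitionMatrix(tissue=tissue, genes=genes, matrix=p.tocsr())


def build_all_tissues(
    interactions: InteractionSet,
    loc: LocalizationMap,
    abund: AbundanceMatrix,
    tissues: Sequence[str] | None = None,
    floor: float = DEFAULT_FLOOR,
    mapping: Mapping[str, float] = DEFAULT_ABUNDANCE_MAPPING,
    permissive: bool = False,
) -> dict[str, TissueTransitionMatrix]:
    """One transition matrix per tissue; matrices differ only through abundance."""
    tissues = abund.tissues if tissues is None else tuple(tissues)
    unknown = set(tissues) - set(abund.tissues)
    if unknown:
        raise ValueError(f"unknown tissue labels: {sorted(unknown)}")
    return {
        t: build_transition_matrix(interactions, loc, abund, t, floor, mapping,
                                   permissive)
        for t in tissues
    }
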