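"""Evidence matrix E and the initial signal vector S.

E is a binary gene x omics-layer matrix: E[i, j] = 1 if gene i is a
significant hit in layer j (curated risk-gene list, differential methylation,
differential expression, differential splicing, ...). The initial signal for
gene i is the row sum S_i = sum_j E[i, j]; for example a gene that is both
differentially expressed and differentially methylated starts with S_i = 2.
Genes with S_i >= 1 form the seed set from which signal diffuses.

Hit lists arrive pre-thresholded (e.g. FDR < 0.05 for transcriptome layers,
5e-8 for genome-wide association loci); the module records threshold
descriptions as metadata but never re-applies them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceMatrix",
    "build_evidence_matrix",
    "build_signal_vector",
    "summarize_signal_distribution",
]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Binary gene x layer matrix plus per-layer threshold notes."""

    table: pd.DataFrame  # genes x layers, values 0/1
    thresholds: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.columns.duplicated().any():
            raise ValueError("layer labels must be unique")
        vals = self.table.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("evidence entries must be 0 or 1")

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.table.index)


def build_evidence_matrix(
    universe: Sequence[str],
    layers: Sequence[tuple[str, Iterable[str]]],
    thresholds: Mapping[str, str] | None = None,
    permissive: bool = False,
) -> EvidenceMatrix:
    """Assemble E from per-layer hit-gene lists.

    Parameters
    ----------
    universe
        Ordered gene symbols defining the row index.
    layers
        ``(label, hit_genes)`` pairs, one per omics layer.
    thresholds
        Optional per-layer description of the significance cut-off that
        produced the hit list (stored verbatim, never applied).
    permissive
        If true, hit genes outside the universe are dropped with a warning
        instead of raising.
    """
    labels = [lab for lab, _ in layers]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate layer labels")
    known = set(universe)
    table = pd.DataFrame(0, index=list(universe), columns=labels, dtype=int)
    for label, hits in layers:
        for gene in hits:
            if gene not in known:
                if permissive:
                    logger.warning("layer %s: dropping unknown gene %s", label, gene)
                    continue
                raise ValueError(f"layer {label!r}: hit gene {gene!r} not in universe")
            table.at[gene, label] = 1
    return EvidenceMatrix(table=table, thresholds=dict(thresholds or {}))


def build_signal_vector(e: EvidenceMatrix | pd.DataFrame) -> pd.Series:
    """Initial signal S_i = row sum of the evidence matrix for gene i."""
    table = e.table if isinstance(e, EvidenceMatrix) else e
    s = table.sum(axis=1).astype(int)
    s.name = "signal"
    return s


def summarize_signal_distribution(s: pd.Series) -> pd.DataFrame:
    """Count and fraction of seed genes at each initial intensity level.

    Fractions are taken over the seed set (genes with S_i >= 1) and sum to 1.
    """
    seeds = s[s >= 1]
    if seeds.empty:
        raise ValueError("empty seed set: no gene carries initial signal")
    counts = seeds.value_counts().sort_index()
    out = pd.DataFrame({
        "intensity": counts.index.astype(int),
        "count": counts.to_numpy(),
    })
    out["fraction"] = out["count"] / out["count"].sum()
    return out.reset_index(drop=True)
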