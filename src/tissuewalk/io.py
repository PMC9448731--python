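"""TSV readers and writers for every pipeline artifact.

All tables are UTF-8 TSV with one header row; gene symbols are
case-sensitive. Sparse matrices use coordinate triples. Each writer's output
round-trips through the matching reader to an equal in-memory value.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .interactome import (
    AbundanceMatrix,
    InteractionSet,
    LocalizationMap,
    TissueTransitionMatrix,
)

__all__ = [
    "read_edge_list", "write_edge_list",
    "read_localization", "write_localization",
    "read_abundance", "write_abundance",
    "read_evidence", "write_evidence",
    "read_gene_set", "write_gene_set",
    "read_expression", "write_expression",
    "read_transition_matrix", "write_transition_matrix",
    "read_matrix_tsv", "write_matrix_tsv",
    "write_manifest", "read_manifest",
]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Raw edge records, duplicates preserved (dedup is the merge stage's job)."""
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["gene_a", "gene_b", "source"]:
            raise FormatError(f"{path}: expected header gene_a\tgene_b\tsource")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3 or any(not c.strip() for c in row[:3]):
                raise FormatError(f"{path}: malformed row at line {lineno}: {row!r}")
            rows.append((row[0].strip(), row[1].strip(), row[2].strip()))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"])


def write_edge_list(path: str | Path, edges: pd.DataFrame | InteractionSet) -> None:
    if isinstance(edges, InteractionSet):
        df = edges.to_frame().rename(columns={"sources": "source"})
    else:
        df = edges[["gene_a", "gene_b", "source"]]
    df.to_csv(path, sep="\t", index=False)


def read_localization(path: str | Path, vocabulary: Sequence[str] | None = None) -> LocalizationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "domains"]:
        raise FormatError(f"{path}: expected header gene\tdomains")
    mapping = {
        row.gene: frozenset(row.domains.split(";"))
        for row in df.itertuples(index=False)
    }
    if vocabulary is None:
        vocabulary = tuple(sorted({d for doms in mapping.values() for d in doms}))
    return LocalizationMap(domains=mapping, vocabulary=tuple(vocabulary))


def write_localization(path: str | Path, loc: LocalizationMap) -> None:
    rows = [(g, ";".join(sorted(doms))) for g, doms in sorted(loc.domains.items())]
    pd.DataFrame(rows, columns=["gene", "domains"]).to_csv(path, sep="\t", index=False)


def read_abundance(path: str | Path) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).rename_axis(None)
    return AbundanceMatrix(levels=df)


def write_abundance(path: str | Path, abund: AbundanceMatrix) -> None:
    abund.levels.to_csv(path, sep="\t", index_label="gene")


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Wide binary evidence table: gene index, one 0/1 column per layer."""
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(None).astype(int)


def write_evidence(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


def read_gene_set(path: str | Path) -> tuple[str, ...]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path, encoding="utf-8") as fh:
        return tuple(
            line.strip() for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        )


def write_gene_set(path: str | Path, genes: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_expression(path: str | Path, metadata_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    expr = pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "region", "stage_bin"}
    if not required <= set(meta.columns):
        raise FormatError(f"{metadata_path}: metadata needs columns {sorted(required)}")
    missing = set(expr.columns) - set(meta["sample_id"])
    if missing:
        raise FormatError(f"{metadata_path}: samples without metadata: "
                          f"{sorted(missing)[:3]}")
    return expr, meta


def write_expression(path: str | Path, metadata_path: str | Path,
                     expr: pd.DataFrame, metadata: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
    metadata.to_csv(metadata_path, sep="\t", index=False)


def write_transition_matrix(path: str | Path, p: TissueTransitionMatrix) -> None:
    """Sparse coordinate TSV: row_gene, col_gene, probability."""
    coo = p.matrix.tocoo()
    rows = [
        (p.genes[i], p.genes[j], repr(float(v)))
        for i, j, v in zip(coo.row, coo.col, coo.data)
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# tissue={p.tissue}\n")
        fh.write("row_gene\tcol_gene\tprobability\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def read_transition_matrix(path: str | Path, genes: Sequence[str]) -> TissueTransitionMatrix:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# tissue="):
            raise FormatError(f"{path}: missing tissue comment line")
        tissue = first.strip().split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t")
    idx = {g: i for i, g in enumerate(genes)}
    try:
        r = [idx[g] for g in df["row_gene"]]
        c = [idx[g] for g in df["col_gene"]]
    except KeyError as err:
        raise FormatError(f"{path}: unknown gene {err.args[0]!r}") from err
    n = len(genes)
    m = sparse.coo_matrix((df["probability"].to_numpy(float), (r, c)),
                          shape=(n, n)).tocsr()
    return TissueTransitionMatrix(tissue=tissue, genes=tuple(genes), matrix=m)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Dense gene x column matrix (intensities, expression summaries)."""
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(None)


def write_matrix_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n", encoding="utf-8")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
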