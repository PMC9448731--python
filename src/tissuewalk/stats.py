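"""Enrichment and differential-expression statistics for candidate gene sets.

Covers the downstream battery applied to brain-high candidates: proportion
maps over annotation categories (micro-domains, cell-types, regions), pooled
two-proportion z-tests between two candidate sets, one-sided hypergeometric
(Fisher) over-enrichment of set overlaps, argmax tissue assignment with
per-tissue enrichment, prenatal-vs-postnatal Welch t-tests per brain region
with Benjamini-Hochberg FDR control, and intersections with per-cell-type DE
gene lists.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_proportions",
    "two_proportion_ztest",
    "fisher_overlap",
    "max_tissue_assignment",
    "tissue_enrichment",
    "prenatal_postnatal_de",
    "de_region_summary",
    "bh_fdr",
    "intersect_with_celltype_de",
    "percent",
    "PRENATAL_BINS",
    "POSTNATAL_BINS",
]

# stage-bin vocabulary shared with the synthetic generator
from .synthetic import PRENATAL_BINS, POSTNATAL_BINS  # noqa: E402


def percent(count: float, total: float, ndigits: int = 0) -> float:
    """Rounded percentage ``100 * count / total`` as printed in reports."""
    if total <= 0:
        raise ValueError("total must be positive")
    value = 100.0 * count / total
    return round(value, ndigits) if ndigits else float(round(value))


def enrichment_proportions(
    gene_set: Iterable[str],
    annotation: Mapping[str, Iterable[str] | str],
) -> pd.DataFrame:
    """Count and proportion of a gene set per annotation label.

    ``annotation`` maps gene -> label or iterable of labels (a gene may carry
    several micro-domains or cell-types). Proportions are relative to the
    gene-set size, so multi-label genes contribute to several rows and the
    proportions need not sum to one.
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValueError("empty gene set")
    counts: dict[str, int] = {}
    for gene in genes:
        labels = annotation.get(gene, ())
        if isinstance(labels, str):
            labels = (labels,)
        for lab in set(labels):
            counts[lab] = counts.get(lab, 0) + 1
    out = pd.DataFrame(
        sorted(counts.items()), columns=["label", "count"]
    )
    out["proportion"] = out["count"] / len(genes)
    return out


class ZTestResult(NamedTuple):
    z: float
    pvalue: float
    degenerate: bool = False


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)) with the pooled proportion
    p = (x1 + x2) / (n1 + n2). When the pooled proportion is 0 or 1 the
    statistic is undefined; it is reported as z = 0, p = 1 with the
    ``degenerate`` flag set.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(z=0.0, pvalue=1.0, degenerate=True)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ZTestResult(z=z, pvalue=p, degenerate=False)


class FisherResult(NamedTuple):
    overlap: int
    odds_ratio: float
    pvalue: float
    continuity: bool = False


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe_size: int,
) -> FisherResult:
    """One-sided over-enrichment of the overlap of two gene sets.

    The p-value is the upper hypergeometric tail P(X >= k) of the 2x2 table;
    the odds ratio is computed from the table counts, with a 0.5 continuity
    correction (flagged) when any cell is zero.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(a & b)
    n_a, n_b = len(a), len(b)
    p = float(sps.hypergeom.sf(k - 1, universe_size, n_a, n_b))
    # 2x2 table: in-A/in-B, in-A/not-B, not-A/in-B, not-A/not-B
    t11, t12 = k, n_a - k
    t21, t22 = n_b - k, universe_size - n_a - n_b + k
    continuity = 0 in (t11, t12, t21, t22)
    if continuity:
        t11, t12, t21, t22 = (t + 0.5 for t in (t11, t12, t21, t22))
    odds = (t11 * t22) / (t12 * t21)
    return FisherResult(overlap=k, odds_ratio=float(odds), pvalue=p,
                        continuity=continuity)


def max_tissue_assignment(expr: pd.DataFrame) -> pd.Series:
    """Assign each gene the tissue in which it is expressed highest.

    Exact ties go to the first tissue in column order (logged); genes with an
    all-zero row are excluded with a warning.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    vals = expr.to_numpy(dtype=float)
    rowmax = vals.max(axis=1)
    zero = rowmax == 0
    if zero.any():
        logger.warning("excluding %d genes with all-zero expression",
                       int(zero.sum()))
    ties = (vals == rowmax[:, None]).sum(axis=1) > 1
    if (ties & ~zero).any():
        logger.warning("%d genes had tied maxima; first tissue in column "
                       "order used", int((ties & ~zero).sum()))
    idx = vals.argmax(axis=1)
    assigned = pd.Series(
        [expr.columns[j] for j in idx], index=expr.index, name="max_tissue"
    )
    return assigned[~zero]


def tissue_enrichment(
    assignment: pd.Series,
    query_set: Iterable[str],
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Per-tissue over-enrichment of a query set among argmax-assigned genes."""
    query = set(query_set)
    n = universe_size if universe_size is not None else len(assignment)
    rows = []
    for tissue, genes in assignment.groupby(assignment).groups.items():
        res = fisher_overlap(set(genes), query, n)
        rows.append((tissue, len(genes), res.overlap, res.odds_ratio, res.pvalue))
    out = pd.DataFrame(rows, columns=["tissue", "n_assigned", "overlap",
                                      "odds_ratio", "pvalue"])
    out["qvalue"] = bh_fdr(out["pvalue"].tolist())
    return out.sort_values("pvalue").reset_index(drop=True)


def _stage_group(stage_bin: str) -> str:
    if stage_bin in PRENATAL_BINS:
        return "prenatal"
    if stage_bin in POSTNATAL_BINS:
        return "postnatal"
    raise ValueError(f"unknown stage bin {stage_bin!r}")


def prenatal_postnatal_de(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    region: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test of prenatal vs postnatal expression within one region.

    Per gene: two-sided unequal-variance t-test between the region's prenatal
    and postnatal samples, then Benjamini-Hochberg correction across genes of
    that region. A gene is DE when q < ``alpha``.
    """
    meta = metadata[metadata["region"] == region]
    if meta.empty:
        raise ValueError(f"no samples for region {region!r}")
    groups = meta["stage_bin"].map(_stage_group)
    pre = meta.loc[groups == "prenatal", "sample_id"]
    post = meta.loc[groups == "postnatal", "sample_id"]
    if len(pre) < 2 or len(post) < 2:
        raise ValueError(
            f"region {region!r}: need >= 2 prenatal and postnatal samples "
            f"(got {len(pre)}/{len(post)})"
        )
    x = expr[list(pre)].to_numpy(dtype=float)
    y = expr[list(post)].to_numpy(dtype=float)
    tstat, pval = sps.ttest_ind(x, y, axis=1, equal_var=False)
    qval = bh_fdr(pval.tolist())
    out = pd.DataFrame({
        "gene": expr.index,
        "region": region,
        "t": tstat,
        "pvalue": pval,
        "qvalue": qval,
    })
    out["de"] = out["qvalue"] < alpha
    return out


def de_region_summary(
    de_tables: Mapping[str, pd.DataFrame],
    query_set: Iterable[str],
) -> pd.DataFrame:
    """Per-gene number of regions in which a query gene is DE.

    Summarizes, for a gene set of interest, how many regions call each gene
    DE (0..n_regions); genes DE in at least one region are the developmental
    DE set.
    """
    query = list(dict.fromkeys(query_set))
    n_regions = pd.Series(0, index=query, dtype=int)
    for region, table in de_tables.items():
        de_genes = set(table.loc[table["de"], "gene"])
        n_regions += pd.Series(
            [g in de_genes for g in query], index=query, dtype=int
        )
    return pd.DataFrame({"gene": query, "n_de_regions": n_regions.to_numpy()})


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def intersect_with_celltype_de(
    novel_candidates: Iterable[str],
    celltype_de: Mapping[str, Iterable[str]],
    cell_class: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Intersect novel candidates with per-cell-type DE gene lists.

    Optionally aggregates by a cell-type -> class map (e.g. neuronal vs
    glial); the returned table has one row per cell type with the exact
    intersection.
    """
    novel = set(novel_candidates)
    rows = []
    for celltype, de_genes in celltype_de.items():
        inter = sorted(novel & set(de_genes))
        rows.append((
            celltype,
            (cell_class or {}).get(celltype, ""),
            len(inter),
            ";".join(inter),
        ))
    return pd.DataFrame(rows, columns=["cell_type", "cell_class",
                                       "n_intersection", "genes"])
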