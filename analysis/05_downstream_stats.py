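#!/usr/bin/env python
"""Downstream statistics on the brain-high candidate sets.

Reproduces the statistical battery applied to candidates: micro-domain
proportion maps with pooled two-proportion z-tests between known and novel
sets, one-sided Fisher/hypergeometric marker-set enrichment, and
prenatal-vs-postnatal Welch DE per region with BH FDR, summarized over the
candidate set.

Writes ``domain_proportions.tsv``, ``marker_enrichment.tsv``, ``dev_de.tsv``
and ``dev_de_candidates.tsv`` under ``scratch/pipeline/outputs``; the small
summary tables are also copied to ``results/``.
"""

import logging
from pathlib import Path

import pandas as pd

from tissuewalk import io
from tissuewalk import stats as tw

WORKDIR = Path(__file__).resolve().parents[1] / "scratch" / "pipeline"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    ind, outd = WORKDIR / "inputs", WORKDIR / "outputs"

    universe = io.read_gene_set(ind / "universe.txt")
    loc = io.read_localization(ind / "localization.tsv")
    table = pd.read_csv(outd / "candidates.tsv", sep="\t")
    known = table.loc[table.status == "known", "gene"].tolist()
    novel = table.loc[table.status == "novel", "gene"].tolist()

    # micro-domain proportion maps, known vs novel, with z-tests
    annot = {g: loc.domains[g] for g in table.gene if g in loc.domains}
    rows = []
    prop_known = tw.enrichment_proportions(known, annot) if known else None
    prop_novel = tw.enrichment_proportions(novel, annot) if novel else None
    if prop_known is not None and prop_novel is not None:
        merged = prop_known.merge(prop_novel, on="label",
                                  suffixes=("_known", "_novel"), how="outer") \
            .fillna(0)
        for r in merged.itertuples(index=False):
            z = tw.two_proportion_ztest(int(r.count_known), max(len(known), 1),
                                        int(r.count_novel), max(len(novel), 1))
            rows.append((r.label, r.count_known, r.proportion_known,
                         r.count_novel, r.proportion_novel, z.z, z.pvalue))
        dom = pd.DataFrame(rows, columns=[
            "domain", "n_known", "prop_known", "n_novel", "prop_novel",
            "z", "pvalue"])
        dom.to_csv(outd / "domain_proportions.tsv", sep="\t", index=False)
        RESULTS.mkdir(exist_ok=True)
        dom.to_csv(RESULTS / "domain_proportions.tsv", sep="\t", index=False)
        n_diff = int((dom.pvalue < 0.05).sum())
        top = dom.sort_values("prop_novel", ascending=False).head(5)
        print(f"micro-domain proportions: top domains for novel candidates: "
              + ", ".join(f"{r.domain} ({100 * r.prop_novel:.0f}%)"
                          for r in top.itertuples(index=False)))
        print(f"domains with significantly different known-vs-novel "
              f"proportions (z-test, 0.05): {n_diff}/{len(dom)}")

    # marker-set Fisher enrichment of the full candidate set
    rows = []
    for path in sorted(ind.glob("markers_*.txt")):
        name = path.stem.removeprefix("markers_")
        markers = io.read_gene_set(path)
        res = tw.fisher_overlap(table.gene.tolist(), markers, len(universe))
        rows.append((name, len(markers), res.overlap, res.odds_ratio,
                     res.pvalue))
    if rows:
        mt = pd.DataFrame(rows, columns=["marker_set", "set_size", "overlap",
                                         "odds_ratio", "pvalue"])
        mt["qvalue"] = tw.bh_fdr(mt.pvalue.tolist())
        mt = mt.sort_values("pvalue")
        mt.to_csv(outd / "marker_enrichment.tsv", sep="\t", index=False)
        mt.to_csv(RESULTS / "marker_enrichment.tsv", sep="\t", index=False)
        print("marker-set enrichment (one-sided Fisher):")
        for r in mt.itertuples(index=False):
            print(f"  {r.marker_set}: overlap {r.overlap}, OR "
                  f"{r.odds_ratio:.1f}, p={r.pvalue:.2e}")

    # prenatal vs postnatal DE per region, summarized over candidates
    expr, meta = io.read_expression(ind / "dev_expression.tsv",
                                    ind / "dev_samples.tsv")
    tables = {region: tw.prenatal_postnatal_de(expr, meta, region)
              for region in sorted(meta.region.unique())}
    de_all = pd.concat(tables.values(), ignore_index=True)
    de_all.to_csv(outd / "dev_de.tsv", sep="\t", index=False)
    summary = tw.de_region_summary(tables, table.gene.tolist())
    summary.to_csv(outd / "dev_de_candidates.tsv", sep="\t", index=False)
    summary.to_csv(RESULTS / "dev_de_candidates.tsv", sep="\t", index=False)
    n_any = int((summary.n_de_regions >= 1).sum())
    print(f"developmental DE: {n_any}/{len(summary)} candidates "
          f"({tw.percent(n_any, max(len(summary), 1)):.0f}%) DE in >= 1 of "
          f"{len(tables)} regions; per-gene DE-region counts range "
          f"{summary.n_de_regions.min()}..{summary.n_de_regions.max()}")


if __name__ == "__main__":
    main()
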