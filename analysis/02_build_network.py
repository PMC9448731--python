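#!/usr/bin/env python
"""Merge the raw edge sources and build per-tissue transition matrices.

Deduplicates the multi-source interactome (canonical unordered pairs,
self-pairs dropped, provenance retained), then weights each edge per tissue
by micro-domain Jaccard co-localization and ordinal protein abundance, and
row-normalizes into Markov transition matrices.

Writes ``outputs/interactome.tsv`` and one coordinate-format matrix per
tissue under ``scratch/pipeline/outputs``.
"""

import logging
from pathlib import Path

from tissuewalk import interactome as it
from tissuewalk import io

WORKDIR = Path(__file__).resolve().parents[1] / "scratch" / "pipeline"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    ind, outd = WORKDIR / "inputs", WORKDIR / "outputs"
    outd.mkdir(exist_ok=True)

    universe = io.read_gene_set(ind / "universe.txt")
    raw = [io.read_edge_list(p) for p in sorted(ind.glob("edges_source_*.tsv"))]
    n_raw = sum(len(r) for r in raw)
    inter = it.merge_and_dedupe(raw, universe)
    io.write_edge_list(outd / "interactome.tsv", inter)
    print(f"merged {n_raw} raw records from {len(raw)} sources into "
          f"{len(inter)} unique interactions "
          f"({n_raw - len(inter)} duplicates/self-pairs removed)")

    loc = io.read_localization(ind / "localization.tsv")
    abund = io.read_abundance(ind / "abundance.tsv")
    matrices = it.build_all_tissues(inter, loc, abund)
    for tissue, p in matrices.items():
        io.write_transition_matrix(outd / f"transition_{tissue}.tsv", p)
    print(f"built {len(matrices)} row-stochastic transition matrices "
          f"({len(universe)} x {len(universe)}) for tissues: "
          f"{', '.join(list(matrices)[:4])}, ...")


if __name__ == "__main__":
    main()
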