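"""End-to-end pipeline: simulate/read inputs, merge, weight, diffuse, select, score.

Each stage reads and writes only its declared TSV artifacts so stages can be
run (and tested) in isolation; :func:`run_pipeline` chains them and writes a
run manifest with the parameter echo and per-tissue convergence times. Given
identical inputs and seed the run is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__, candidates as cand, diffusion, evidence, interactome, io
from . import stats as twstats
from .synthetic import (
    DEFAULT_BRAIN_TISSUES,
    SimulationConfig,
    generate_abundance,
    generate_dev_expression,
    generate_evidence,
    generate_interactome_sources,
    generate_localization,
    generate_marker_sets,
    generate_module,
    generate_universe,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "simulate_inputs", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; flags mirror the CLI."""

    workdir: Path
    brain_tissues: tuple[str, ...] = DEFAULT_BRAIN_TISSUES
    floor: float = interactome.DEFAULT_FLOOR
    abundance_mapping: Mapping[str, float] = field(
        default_factory=lambda: dict(interactome.DEFAULT_ABUNDANCE_MAPPING)
    )
    tol: float = diffusion.DEFAULT_TOL
    max_t: int = diffusion.DEFAULT_MAX_T
    alpha: float = 0.05
    permissive: bool = False
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if not self.brain_tissues:
            raise ValueError("brain tissue subset must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def input_dir(self) -> Path:
        return Path(self.workdir) / "inputs"

    @property
    def output_dir(self) -> Path:
        return Path(self.workdir) / "outputs"


def simulate_inputs(config: PipelineConfig) -> dict:
    """Generate the synthetic cohort and write every pipeline input as TSV."""
    sim = config.simulation
    if sim is None:
        raise ValueError("simulate_inputs requires a SimulationConfig")
    d = config.input_dir
    d.mkdir(parents=True, exist_ok=True)

    universe = generate_universe(sim)
    module = generate_module(universe, sim)
    sources = generate_interactome_sources(universe, module, sim)
    loc = generate_localization(universe, module, sim)
    abund = generate_abundance(universe, module, sim)
    ev = generate_evidence(universe, module, sim)
    expr, meta = generate_dev_expression(universe, sim)
    markers = generate_marker_sets(universe, module, sim)

    io.write_gene_set(d / "universe.txt", universe.genes)
    for k, src in enumerate(sources, start=1):
        io.write_edge_list(d / f"edges_source_{k}.tsv", src)
    io.write_localization(d / "localization.tsv", loc)
    io.write_abundance(d / "abundance.tsv", abund)
    io.write_evidence(d / "evidence.tsv", ev)
    io.write_expression(d / "dev_expression.tsv", d / "dev_samples.tsv", expr, meta)
    for name, genes in markers.items():
        io.write_gene_set(d / f"markers_{name}.txt", sorted(genes))
    io.write_gene_set(d / "module_members.txt", module.member_genes)
    io.write_gene_set(d / "module_seeds.txt", module.seed_genes)
    logger.info("simulated %d genes, %d edge sources, module of %d (%d seeds)",
                universe.size, len(sources), len(module.member_genes),
                len(module.seed_genes))
    return {"universe": universe, "module": module, "n_sources": len(sources)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run merge -> weight -> diffuse -> select -> stats; return artifact paths.

    Inputs are read back from ``inputs/`` (written beforehand, e.g. by
    :func:`simulate_inputs`), so a run always exercises the declared file
    formats.
    """
    ind, outd = config.input_dir, config.output_dir
    if not ind.is_dir():
        raise ValueError(f"input directory {ind} does not exist")
    outd.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        universe = io.read_gene_set(ind / "universe.txt")
        edge_files = sorted(ind.glob("edges_source_*.tsv"))
        raw_sources = [io.read_edge_list(p) for p in edge_files]
        loc = io.read_localization(ind / "localization.tsv")
        abund = io.read_abundance(ind / "abundance.tsv")
        ev_table = io.read_evidence(ind / "evidence.tsv")
        missing_brain = set(config.brain_tissues) - set(abund.tissues)
        if missing_brain:
            raise ValueError(f"brain tissues missing from abundance matrix: "
                             f"{sorted(missing_brain)}")

        stage = "merge"
        interactions = interactome.merge_and_dedupe(raw_sources, universe)
        io.write_edge_list(outd / "interactome.tsv", interactions)

        stage = "evidence"
        e = evidence.EvidenceMatrix(table=ev_table.reindex(list(universe)).fillna(0).astype(int))
        signal = evidence.build_signal_vector(e)
        seeds = tuple(signal.index[signal >= 1])
        io.write_matrix_tsv(outd / "signal_vector.tsv", signal.to_frame())
        dist = evidence.summarize_signal_distribution(signal)
        dist.to_csv(outd / "signal_distribution.tsv", sep="\t", index=False)

        stage = "weight"
        matrices = interactome.build_all_tissues(
            interactions, loc, abund, floor=config.floor,
            mapping=config.abundance_mapping, permissive=config.permissive,
        )

        stage = "diffuse"
        intensity, profiles = diffusion.diffuse_all_tissues(
            signal.reindex(list(abund.genes)).fillna(0),
            matrices, tol=config.tol, max_t=config.max_t,
        )
        io.write_matrix_tsv(outd / "intensity_matrix.tsv", intensity)
        conv = pd.DataFrame(
            [(t, p.t, p.trace[-1], p.converged) for t, p in profiles.items()],
            columns=["tissue", "t", "final_change", "converged"],
        )
        conv.to_csv(outd / "convergence.tsv", sep="\t", index=False)

        stage = "select"
        selected = cand.select_brain_high(intensity, config.brain_tissues)
        selected = cand.split_known_novel(selected, seeds)
        selected.to_frame().to_csv(outd / "candidates.tsv", sep="\t", index=False)

        stage = "neighborhood"
        if selected.novel:
            hood = cand.extract_neighborhood(interactions, selected.novel, seeds)
            pd.DataFrame(hood.edges, columns=["gene_a", "gene_b"]).to_csv(
                outd / "neighborhood_edges.tsv", sep="\t", index=False
            )
        else:
            hood = None

        stage = "stats"
        stats_paths = _downstream_stats(config, universe, loc, selected)

        manifest = {
            "version": __version__,
            "parameters": {
                "brain_tissues": list(config.brain_tissues),
                "floor": config.floor,
                "abundance_mapping": dict(config.abundance_mapping),
                "tol": config.tol,
                "max_t": config.max_t,
                "alpha": config.alpha,
                "permissive": config.permissive,
                "rng_seed": config.simulation.rng_seed if config.simulation else None,
            },
            "n_genes": len(universe),
            "n_unique_interactions": len(interactions),
            "n_seed_genes": len(seeds),
            "n_candidates": len(selected.selected),
            "n_known": len(selected.known),
            "n_novel": len(selected.novel),
            "convergence_times": {t: p.t for t, p in profiles.items()},
            "neighborhood": None if hood is None else {
                "n_edges": hood.n_edges,
                "n_neighbors": len(hood.neighbors),
                "fraction_reference": hood.fraction_reference,
            },
        }
        io.write_manifest(outd / "manifest.json", manifest)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    logger.info("pipeline complete: %d candidates (%d known, %d novel)",
                len(selected.selected), len(selected.known), len(selected.novel))
    return {"manifest": outd / "manifest.json", "candidates": selected,
            "intensity": intensity, "profiles": profiles,
            "interactions": interactions, "seeds": seeds, **stats_paths}


def _downstream_stats(config: PipelineConfig, universe: Sequence[str],
                      loc, selected) -> dict:
    """Localization enrichment of candidates, marker overlaps, regional DE."""
    ind, outd = config.input_dir, config.output_dir
    out: dict = {}
    if selected.selected:
        prop = twstats.enrichment_proportions(
            selected.selected, {g: loc.domains[g] for g in selected.selected
                                if g in loc.domains},
        )
        prop.to_csv(outd / "domain_enrichment.tsv", sep="\t", index=False)
        out["domain_enrichment"] = prop

    marker_files = sorted(ind.glob("markers_*.txt"))
    if marker_files and selected.selected:
        rows = []
        for path in marker_files:
            name = path.stem.removeprefix("markers_")
            markers = io.read_gene_set(path)
            res = twstats.fisher_overlap(selected.selected, markers, len(universe))
            rows.append((name, len(markers), res.overlap, res.odds_ratio,
                         res.pvalue))
        marker_table = pd.DataFrame(
            rows, columns=["marker_set", "set_size", "overlap", "odds_ratio",
                           "pvalue"])
        marker_table["qvalue"] = twstats.bh_fdr(marker_table["pvalue"].tolist())
        marker_table.to_csv(outd / "marker_enrichment.tsv", sep="\t", index=False)
        out["marker_enrichment"] = marker_table

    expr_path = ind / "dev_expression.tsv"
    if expr_path.exists():
        expr, meta = io.read_expression(expr_path, ind / "dev_samples.tsv")
        tables = {}
        for region in sorted(meta["region"].unique()):
            tables[region] = twstats.prenatal_postnatal_de(
                expr, meta, region, alpha=config.alpha)
        de_all = pd.concat(tables.values(), ignore_index=True)
        de_all.to_csv(outd / "dev_de.tsv", sep="\t", index=False)
        if selected.selected:
            summary = twstats.de_region_summary(tables, selected.selected)
            summary.to_csv(outd / "dev_de_candidates.tsv", sep="\t", index=False)
            out["dev_de_summary"] = summary
        out["dev_de"] = de_all
    return out
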