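"""Synthetic multi-omics cohort generator with a planted brain-specific module.

Every input the diffusion pipeline consumes can be generated here: multi-source
protein-protein interaction edge lists (with duplicate records for the
deduplication stage to remove), multi-label subcellular localization over a
32-micro-domain vocabulary, four-level ordinal protein abundance across
tissue/cell-type columns, sparse binary omics evidence layers, stage-binned
developmental expression, and cell-type marker gene sets.

A *planted module* — a gene subset with elevated internal connectivity, a
shared micro-domain, and boosted abundance in designated brain tissues — gives
the pipeline a measurable recovery task: a subset of module genes ("seeds")
carries initial evidence, the remainder ("hidden" genes) carries none and must
be found by network diffusion alone.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import (
    ORDINAL_LEVELS,
    AbundanceMatrix,
    LocalizationMap,
)

__all__ = [
    "GeneUniverse",
    "PlantedModule",
    "SimulationConfig",
    "generate_universe",
    "generate_module",
    "generate_interactome_sources",
    "generate_localization",
    "generate_abundance",
    "generate_evidence",
    "generate_dev_expression",
    "generate_marker_sets",
    "DEFAULT_BRAIN_TISSUES",
    "PRENATAL_BINS",
    "POSTNATAL_BINS",
    "DEFAULT_LAYERS",
]

DEFAULT_BRAIN_TISSUES = (
    "cerebral_cortex",
    "cerebellum",
    "caudate",
    "hippocampus",
)

#: omics evidence layers: curated genome hits, epigenome (methylation),
#: transcriptome differential expression, transcriptome differential splicing
DEFAULT_LAYERS = ("genome", "epigenome", "transcriptome_de", "transcriptome_splicing")

#: developmental stage bins; the first three are prenatal (post-conception
#: weeks), the last four postnatal (years)
PRENATAL_BINS = ("0-12_pcw", "13-24_pcw", "25-36_pcw")
POSTNATAL_BINS = ("0-2_yr", "3-8_yr", "9-16_yr", "17plus_yr")

#: distribution of the number of evidence layers hit per seed gene; heavily
#: skewed toward single-layer evidence, as observed for curated risk loci
SEED_LAYER_COUNT_PROBS = (0.78, 0.15, 0.058, 0.012)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, unique gene symbols; the shared index for every matrix."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ConfigError("gene universe must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("gene symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.genes)

    def index_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class PlantedModule:
    """A designated gene subset used to measure candidate recovery.

    ``seed_genes`` carry initial omics evidence; ``hidden_genes`` carry none
    and can only be reached through diffusion over the network.
    """

    member_genes: tuple[str, ...]
    seed_genes: tuple[str, ...]
    target_tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        members, seeds = set(self.member_genes), set(self.seed_genes)
        if not seeds <= members:
            raise ConfigError("seed_genes must be a subset of member_genes")
        if self.member_genes and not self.target_tissues:
            raise ConfigError("target_tissues must be non-empty")

    @property
    def hidden_genes(self) -> tuple[str, ...]:
        seeds = set(self.seed_genes)
        return tuple(g for g in self.member_genes if g not in seeds)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults describe a desk-scale instance: 500 genes, a planted module of
    50 genes of which 20 are evidence-carrying seeds, and 131 tissue/cell-type
    columns of which four are brain tissues.
    """

    n_genes: int = 500
    n_sources: int = 3
    edge_density: float = 0.02
    duplicate_rate: float = 0.3
    within_module_density: float = 0.1
    n_domains: int = 32
    mean_domains_per_gene: float = 2.0
    module_codomain_prob: float = 0.9
    n_tissues: int = 131
    brain_tissues: tuple[str, ...] = DEFAULT_BRAIN_TISSUES
    n_layers: int = 4
    module_size: int = 50
    seed_fraction: float = 0.4
    abundance_boost: int = 2
    background_hit_rate: float = 0.01
    n_regions: int = 16
    n_stage_reps: int = 3
    de_fraction: float = 0.5
    de_effect: float = 2.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_density", "duplicate_rate", "within_module_density",
                     "module_codomain_prob", "seed_fraction",
                     "background_hit_rate", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if self.module_size > self.n_genes:
            raise ConfigError("module_size exceeds n_genes")
        if self.n_tissues < len(self.brain_tissues):
            raise ConfigError("n_tissues smaller than the brain tissue set")
        if self.n_domains < 1:
            raise ConfigError("n_domains must be >= 1")
        if self.n_sources < 1:
            raise ConfigError("n_sources must be >= 1")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")

    @property
    def tissue_labels(self) -> tuple[str, ...]:
        extra = self.n_tissues - len(self.brain_tissues)
        return self.brain_tissues + tuple(f"tissue_{i:03d}" for i in range(1, extra + 1))

    @property
    def domain_labels(self) -> tuple[str, ...]:
        return tuple(f"domain_{i:02d}" for i in range(1, self.n_domains + 1))

    @property
    def layer_labels(self) -> tuple[str, ...]:
        if self.n_layers == len(DEFAULT_LAYERS):
            return DEFAULT_LAYERS
        return tuple(f"layer_{i}" for i in range(1, self.n_layers + 1))


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # one independent stream per generator call, derived from the single
    # config seed; crc32 keeps the stream label stable across processes
    seed = np.random.SeedSequence([config.rng_seed, zlib.crc32(stream.encode())])
    return np.random.default_rng(seed)


def generate_universe(config: SimulationConfig) -> GeneUniverse:
    """Synthetic gene symbols, stable across calls with the same config."""
    if config.n_genes < 2:
        raise ConfigError("n_genes must be >= 2")
    width = max(5, len(str(config.n_genes)))
    return GeneUniverse(tuple(f"SYNG{i:0{width}d}" for i in range(1, config.n_genes + 1)))


def generate_module(universe: GeneUniverse, config: SimulationConfig) -> PlantedModule:
    """Sample the planted module and flag a seed subset of it."""
    rng = _rng(config, "module")
    members = rng.choice(universe.genes, size=config.module_size, replace=False)
    members = tuple(sorted(members))
    n_seeds = int(round(config.seed_fraction * config.module_size))
    seeds = tuple(sorted(rng.choice(members, size=n_seeds, replace=False))) if members else ()
    return PlantedModule(member_genes=members, seed_genes=seeds,
                         target_tissues=config.brain_tissues)


def generate_interactome_sources(
    universe: GeneUniverse,
    module: PlantedModule,
    config: SimulationConfig,
) -> list[pd.DataFrame]:
    """Raw multi-source edge lists with duplicate and orientation-flipped records.

    The background graph is Erdős–Rényi at ``edge_density``; module genes
    receive an additional, denser internal wiring at ``within_module_density``.
    Each unique edge is emitted into one source; with probability
    ``duplicate_rate`` it is re-emitted into a second source with random
    orientation, so the merge stage has genuine duplicates to remove.
    """
    if universe.size == 0:
        raise ConfigError("empty universe")
    rng = _rng(config, "interactome")

    g = nx.gnp_random_graph(universe.size, config.edge_density,
                            seed=int(rng.integers(2**31)))
    idx = {i: gene for i, gene in enumerate(universe.genes)}
    edges = {tuple(sorted((idx[u], idx[v]))) for u, v in g.edges()}
    # denser planted subgraph
    for a, b in itertools.combinations(sorted(module.member_genes), 2):
        if rng.random() < config.within_module_density:
            edges.add(tuple(sorted((a, b))))

    labels = [f"source_{k}" for k in range(1, config.n_sources + 1)]
    records: dict[str, list[tuple[str, str, str]]] = {lab: [] for lab in labels}
    for a, b in sorted(edges):
        primary = labels[int(rng.integers(config.n_sources))]
        records[primary].append((a, b, primary))
        if config.n_sources > 1 and rng.random() < config.duplicate_rate:
            other = labels[int(rng.integers(config.n_sources))]
            pair = (a, b) if rng.random() < 0.5 else (b, a)
            records[other].append((pair[0], pair[1], other))
    return [
        pd.DataFrame(records[lab], columns=["gene_a", "gene_b", "source"])
        for lab in labels
    ]


def generate_localization(
    universe: GeneUniverse,
    module: PlantedModule,
    config: SimulationConfig,
) -> LocalizationMap:
    """Assign each gene >= 1 micro-domain; module genes share ``domain_01``.

    The per-gene domain count is 1 + Poisson(mean - 1); module genes
    additionally carry the designated module domain with probability
    ``module_codomain_prob``, which raises their pairwise Jaccard similarity.
    """
    if config.n_domains < 1:
        raise ConfigError("n_domains must be >= 1")
    rng = _rng(config, "localization")
    vocab = config.domain_labels
    module_domain = vocab[0]
    members = set(module.member_genes)
    mapping: dict[str, frozenset[str]] = {}
    for gene in universe.genes:
        k = 1 + rng.poisson(max(config.mean_domains_per_gene - 1.0, 0.0))
        k = min(k, config.n_domains)
        doms = set(rng.choice(vocab, size=k, replace=False))
        if gene in members and rng.random() < config.module_codomain_prob:
            doms.add(module_domain)
        mapping[gene] = frozenset(doms)
    return LocalizationMap(domains=mapping, vocabulary=vocab)


#: categorical background distribution over the four ordinal abundance levels
ABUNDANCE_LEVEL_PROBS = (0.25, 0.35, 0.25, 0.15)


def generate_abundance(
    universe: GeneUniverse,
    module: PlantedModule,
    config: SimulationConfig,
) -> AbundanceMatrix:
    """Ordinal gene x tissue abundance; module genes boosted in target tissues.

    The boost adds ``abundance_boost`` ordinal levels, clipped at "high", to
    module genes in the module's target (brain) tissues only; with boost 0 the
    module rows are drawn from the same background distribution as everything
    else.
    """
    unknown = set(module.member_genes) - set(universe.genes)
    if unknown:
        raise ConfigError(f"module genes not in universe: {sorted(unknown)[:3]}")
    rng = _rng(config, "abundance")
    tissues = config.tissue_labels
    base = rng.choice(len(ORDINAL_LEVELS), size=(universe.size, len(tissues)),
                      p=ABUNDANCE_LEVEL_PROBS)
    gene_idx = universe.index_of()
    rows = [gene_idx[g] for g in module.member_genes]
    cols = [tissues.index(t) for t in module.target_tissues]
    if rows and cols:
        sub = base[np.ix_(rows, cols)] + config.abundance_boost
        base[np.ix_(rows, cols)] = np.clip(sub, 0, len(ORDINAL_LEVELS) - 1)
    levels = pd.DataFrame(
        np.array(ORDINAL_LEVELS, dtype=object)[base],
        index=list(universe.genes),
        columns=list(tissues),
    )
    return AbundanceMatrix(levels=levels)


def generate_evidence(
    universe: GeneUniverse,
    module: PlantedModule,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Binary gene x layer evidence matrix.

    Every seed gene receives at least one hit, with a layer count drawn from a
    skewed distribution (mostly single-layer evidence). Hidden module genes
    receive exactly zero hits — recovering them is the diffusion task. Genes
    outside the module get a sparse background hit at ``background_hit_rate``.
    """
    if config.seed_fraction == 0 or not module.seed_genes:
        raise ConfigError("seed_fraction=0 leaves no signal to diffuse")
    rng = _rng(config, "evidence")
    layers = config.layer_labels
    e = pd.DataFrame(0, index=list(universe.genes), columns=list(layers), dtype=int)
    probs = np.array(SEED_LAYER_COUNT_PROBS[: config.n_layers], dtype=float)
    probs /= probs.sum()
    for gene in module.seed_genes:
        k = 1 + rng.choice(len(probs), p=probs)
        k = min(k, config.n_layers)
        hit = rng.choice(layers, size=k, replace=False)
        e.loc[gene, hit] = 1
    members = set(module.member_genes)
    for gene in universe.genes:
        if gene in members:
            continue
        if rng.random() < config.background_hit_rate:
            e.loc[gene, layers[int(rng.integers(config.n_layers))]] = 1
    return e


def generate_dev_expression(
    universe: GeneUniverse,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-binned developmental expression with planted prenatal→postnatal DE.

    Returns ``(expression, metadata)``: a gene x sample matrix and a sample
    sidecar with columns ``sample_id, region, stage_bin``. A ``de_fraction``
    of genes gets a postnatal mean shift of ``de_effect`` (random sign, same
    genes in every region); Gaussian noise has sd ``noise_sd``.
    """
    if not 0.0 <= config.de_fraction <= 1.0:
        raise ConfigError("de_fraction outside [0, 1]")
    if config.n_stage_reps < 2:
        raise ConfigError("need >= 2 replicates per stage bin per region")
    rng = _rng(config, "dev_expression")
    regions = tuple(f"region_{i:02d}" for i in range(1, config.n_regions + 1))
    bins = PRENATAL_BINS + POSTNATAL_BINS

    n_de = int(round(config.de_fraction * universe.size))
    de_idx = rng.choice(universe.size, size=n_de, replace=False)
    shift = np.zeros(universe.size)
    shift[de_idx] = config.de_effect * rng.choice([-1.0, 1.0], size=n_de)
    baseline = rng.normal(5.0, 1.0, size=universe.size)

    meta_rows, cols, data = [], [], []
    for region in regions:
        for stage_bin in bins:
            postnatal = stage_bin in POSTNATAL_BINS
            for rep in range(1, config.n_stage_reps + 1):
                sid = f"{region}_{stage_bin}_r{rep}"
                mu = baseline + (shift if postnatal else 0.0)
                data.append(mu + rng.normal(0.0, config.noise_sd, size=universe.size))
                cols.append(sid)
                meta_rows.append((sid, region, stage_bin))
    expr = pd.DataFrame(np.column_stack(data), index=list(universe.genes), columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "region", "stage_bin"])
    return expr, meta


DEFAULT_MARKER_SPECS = {
    "Exc_neurons": (60, "high"),
    "In_neurons": (60, "high"),
    "Oligodendrocytes": (60, "low"),
    "Astrocytes": (60, "low"),
    "Microglia": (60, "low"),
    "Endothelial": (60, "low"),
}


def generate_marker_sets(
    universe: GeneUniverse,
    module: PlantedModule,
    config: SimulationConfig,
    specs: dict[str, tuple[int, int | str]] | None = None,
) -> dict[str, frozenset[str]]:
    """Named cell-type marker sets with configured overlap with the module.

    ``specs`` maps set name to ``(size, overlap)`` where overlap is an exact
    member count or "high"/"low" (half the module / 2 genes). Neuronal sets
    default to high overlap, glial/vascular sets to low.
    """
    specs = dict(DEFAULT_MARKER_SPECS if specs is None else specs)
    rng = _rng(config, "markers")
    members = list(module.member_genes)
    background = [g for g in universe.genes if g not in set(members)]
    out: dict[str, frozenset[str]] = {}
    for name, (size, overlap) in specs.items():
        if overlap == "high":
            overlap = len(members) // 2
        elif overlap == "low":
            overlap = min(2, len(members))
        overlap = int(overlap)
        if overlap > len(members):
            raise ConfigError(f"{name}: requested overlap {overlap} > module size {len(members)}")
        if size > universe.size:
            raise ConfigError(f"{name}: set size {size} > universe size")
        if size < overlap:
            raise ConfigError(f"{name}: set size {size} < overlap {overlap}")
        inside = rng.choice(members, size=overlap, replace=False) if overlap else []
        outside = rng.choice(background, size=size - overlap, replace=False)
        out[name] = frozenset(inside) | frozenset(outside)
    return out
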