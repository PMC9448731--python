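"""Generator contracts: determinism, planted structure, distributional sanity."""

import math

import numpy as np
import pandas as pd
import pytest

from tissuewalk import interactome as it
from tissuewalk import synthetic as syn
from tissuewalk.synthetic import ConfigError, SimulationConfig


def test_universe_unique_and_deterministic():
    cfg = SimulationConfig(n_genes=500, rng_seed=7)
    u1 = syn.generate_universe(cfg)
    u2 = syn.generate_universe(cfg)
    assert u1.genes == u2.genes
    assert len(set(u1.genes)) == 500


def test_universe_degenerate_size_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(n_genes=1)


@pytest.mark.parametrize("field,value", [
    ("edge_density", 1.5),
    ("duplicate_rate", -0.1),
    ("de_fraction", 2.0),
    ("module_size", 1000),
])
def test_config_invariants_enforced(field, value):
    with pytest.raises(ConfigError):
        SimulationConfig(**{field: value})


def test_generators_deterministic_given_seed(small_config):
    cfg = small_config
    uni = syn.generate_universe(cfg)
    mod = syn.generate_module(uni, cfg)
    for gen in (syn.generate_localization, syn.generate_abundance,
                syn.generate_evidence):
        a, b = gen(uni, mod, cfg), gen(uni, mod, cfg)
        if hasattr(a, "levels"):
            pd.testing.assert_frame_equal(a.levels, b.levels)
        elif isinstance(a, pd.DataFrame):
            pd.testing.assert_frame_equal(a, b)
        else:
            assert a.domains == b.domains
    e1, m1 = syn.generate_dev_expression(uni, cfg)
    e2, m2 = syn.generate_dev_expression(uni, cfg)
    pd.testing.assert_frame_equal(e1, e2)
    pd.testing.assert_frame_equal(m1, m2)
    s1 = syn.generate_interactome_sources(uni, mod, cfg)
    s2 = syn.generate_interactome_sources(uni, mod, cfg)
    for a, b in zip(s1, s2):
        pd.testing.assert_frame_equal(a, b)


def test_edge_count_matches_binomial_expectation():
    """ER background: observed unique edge count within 3 sd of Binomial."""
    cfg = SimulationConfig(n_genes=100, edge_density=0.05, module_size=0,
                           duplicate_rate=0.0, n_sources=1, seed_fraction=0.0,
                           rng_seed=3)
    uni = syn.generate_universe(cfg)
    mod = syn.PlantedModule(member_genes=(), seed_genes=(),
                            target_tissues=cfg.brain_tissues)
    sources = syn.generate_interactome_sources(uni, mod, cfg)
    n_pairs = math.comb(100, 2)
    expected = 0.05 * n_pairs
    sd = math.sqrt(n_pairs * 0.05 * 0.95)
    observed = len(sources[0])
    assert abs(observed - expected) <= 3 * sd


def test_duplicate_rate_zero_single_source_has_no_duplicates():
    cfg = SimulationConfig(n_genes=80, duplicate_rate=0.0, n_sources=1,
                           module_size=10, rng_seed=5)
    uni = syn.generate_universe(cfg)
    mod = syn.generate_module(uni, cfg)
    (src,) = syn.generate_interactome_sources(uni, mod, cfg)
    pairs = [tuple(sorted((a, b))) for a, b in zip(src.gene_a, src.gene_b)]
    assert len(pairs) == len(set(pairs))
    merged = it.merge_and_dedupe([src], uni.genes)
    assert len(merged) == len(src)


def test_forced_duplication_creates_cross_source_repeats():
    cfg = SimulationConfig(n_genes=80, duplicate_rate=1.0, n_sources=2,
                           module_size=10, rng_seed=5)
    uni = syn.generate_universe(cfg)
    mod = syn.generate_module(uni, cfg)
    sources = syn.generate_interactome_sources(uni, mod, cfg)
    all_pairs = [
        tuple(sorted((a, b)))
        for src in sources for a, b in zip(src.gene_a, src.gene_b)
    ]
    # with duplicate_rate=1 every unique edge is emitted twice
    assert len(all_pairs) == 2 * len(set(all_pairs))


def test_localization_every_gene_has_domain(small_instance):
    loc = small_instance["localization"]
    for gene in small_instance["universe"].genes:
        assert loc.domains[gene]


def test_single_domain_vocabulary_forces_colocalization():
    cfg = SimulationConfig(n_genes=30, n_domains=1, module_size=5,
                           mean_domains_per_gene=1.0, rng_seed=2)
    uni = syn.generate_universe(cfg)
    mod = syn.generate_module(uni, cfg)
    loc = syn.generate_localization(uni, mod, cfg)
    assert all(doms == frozenset(("domain_01",)) for doms in loc.domains.values())


def test_forced_codomain_shares_module_domain():
    cfg = SimulationConfig(n_genes=60, module_size=15, module_codomain_prob=1.0,
                           rng_seed=4)
    uni = syn.generate_universe(cfg)
    mod = syn.generate_module(uni, cfg)
    loc = syn.generate_localization(uni, mod, cfg)
    module_domain = cfg.domain_labels[0]
    assert all(module_domain in loc.domains[g] for g in mod.member_genes)


def test_mean_domains_per_gene_near_target():
    cfg = SimulationConfig(n_genes=200, module_size=0, seed_fraction=0.0,
                           mean_domains_per_gene=2.0, rng_seed=5)
    uni = syn.generate_universe(cfg)
    mod = syn.PlantedModule(member_genes=(), seed_genes=(),
                            target_tissues=cfg.brain_tissues)
    loc = syn.generate_localization(uni, mod, cfg)
    mean = np.mean([len(d) for d in loc.domains.values()])
    assert 1.7 <= mean <= 2.3


def test_abundance_boost_elevates_brain_columns(small_instance):
    cfg, mod = small_instance["config"], small_instance["module"]
    levels = small_instance["abundance"].levels
    rank = {lev: i for i, lev in enumerate(it.ORDINAL_LEVELS)}
    module_rows = levels.loc[list(mod.member_genes)].map(rank.get)
    brain = list(cfg.brain_tissues)
    non_brain = [t for t in levels.columns if t not in set(brain)]
    assert module_rows[brain].to_numpy().mean() > module_rows[non_brain].to_numpy().mean()


def test_abundance_boost_zero_leaves_module_at_background():
    base = dict(n_genes=200, module_size=40, n_tissues=10, rng_seed=9)
    cfg0 = SimulationConfig(abundance_boost=0, **base)
    uni = syn.generate_universe(cfg0)
    mod = syn.generate_module(uni, cfg0)
    levels = syn.generate_abundance(uni, mod, cfg0).levels
    rank = {lev: i for i, lev in enumerate(it.ORDINAL_LEVELS)}
    module_mean = levels.loc[list(mod.member_genes)].map(rank.get).to_numpy().mean()
    bg = [g for g in uni.genes if g not in set(mod.member_genes)]
    bg_mean = levels.loc[bg].map(rank.get).to_numpy().mean()
    assert abs(module_mean - bg_mean) < 0.25


def test_forced_boost_saturates_at_high():
    cfg = SimulationConfig(n_genes=60, module_size=10, abundance_boost=3,
                           n_tissues=8, rng_seed=1)
    uni = syn.generate_universe(cfg)
    mod = syn.generate_module(uni, cfg)
    levels = syn.generate_abundance(uni, mod, cfg).levels
    block = levels.loc[list(mod.member_genes), list(mod.target_tissues)]
    assert (block == "high").all().all()


def test_evidence_hidden_genes_carry_zero_signal(small_instance):
    ev = small_instance["evidence"]
    mod = small_instance["module"]
    assert (ev.loc[list(mod.hidden_genes)].sum(axis=1) == 0).all()
    assert (ev.loc[list(mod.seed_genes)].sum(axis=1) >= 1).all()


def test_evidence_requires_seeds():
    cfg = SimulationConfig(n_genes=50, module_size=10, seed_fraction=0.0,
                           rng_seed=1)
    uni = syn.generate_universe(cfg)
    mod = syn.generate_module(uni, cfg)
    with pytest.raises(ConfigError):
        syn.generate_evidence(uni, mod, cfg)


def test_dev_expression_shape_and_metadata(small_instance):
    cfg, uni = small_instance["config"], small_instance["universe"]
    expr, meta = syn.generate_dev_expression(uni, cfg)
    assert expr.shape == (cfg.n_genes, cfg.n_regions * 7 * cfg.n_stage_reps)
    assert set(meta.columns) == {"sample_id", "region", "stage_bin"}
    assert set(meta.stage_bin) == set(syn.PRENATAL_BINS + syn.POSTNATAL_BINS)
    # every (region, bin) cell has the configured replicate count
    counts = meta.groupby(["region", "stage_bin"]).size()
    assert (counts == cfg.n_stage_reps).all()


def test_marker_sets_exact_configured_overlap(small_instance):
    cfg, uni, mod = (small_instance["config"], small_instance["universe"],
                     small_instance["module"])
    half = len(mod.member_genes) // 2
    sets = syn.generate_marker_sets(uni, mod, cfg,
                                    specs={"neuronal": (30, half),
                                           "glial": (30, 0)})
    assert len(sets["neuronal"] & set(mod.member_genes)) == half
    assert not sets["glial"] & set(mod.member_genes)


def test_marker_overlap_larger_than_module_rejected(small_instance):
    cfg, uni, mod = (small_instance["config"], small_instance["universe"],
                     small_instance["module"])
    with pytest.raises(ConfigError):
        syn.generate_marker_sets(uni, mod, cfg,
                                 specs={"bad": (50, len(mod.member_genes) + 1)})


def test_planted_module_edges_weigh_more_in_brain(small_instance):
    """Planted-structure contract: module-internal edges carry strictly higher
    mean transition weight than background edges in a brain-tissue matrix."""
    inst = small_instance
    cfg, mod = inst["config"], inst["module"]
    p = it.build_transition_matrix(inst["interactions"], inst["localization"],
                                   inst["abundance"], cfg.brain_tissues[0])
    idx = {g: i for i, g in enumerate(p.genes)}
    members = set(mod.member_genes)
    dense = p.matrix.toarray()
    module_w, background_w = [], []
    for a, b in inst["interactions"].edges:
        w = dense[idx[a], idx[b]]
        (module_w if a in members and b in members else background_w).append(w)
    assert np.mean(module_w) > np.mean(background_w)
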