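import pandas as pd
import pytest

from tissuewalk import interactome as it
from tissuewalk import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.SimulationConfig:
    """A fast 120-gene instance with 12 tissues for unit-level checks."""
    # edge_density 0.06 keeps the 120-gene graph in the connected regime
    # (mean degree ~7), avoiding oscillation on tiny tree components
    return syn.SimulationConfig(
        n_genes=120, n_tissues=12, module_size=20, seed_fraction=0.5,
        edge_density=0.06, n_regions=2, rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_instance(small_config):
    """Fully generated cohort: universe, module, merged network, annotations."""
    cfg = small_config
    universe = syn.generate_universe(cfg)
    module = syn.generate_module(universe, cfg)
    sources = syn.generate_interactome_sources(universe, module, cfg)
    interactions = it.merge_and_dedupe(sources, universe.genes)
    loc = syn.generate_localization(universe, module, cfg)
    abund = syn.generate_abundance(universe, module, cfg)
    ev = syn.generate_evidence(universe, module, cfg)
    return {
        "config": cfg,
        "universe": universe,
        "module": module,
        "sources": sources,
        "interactions": interactions,
        "localization": loc,
        "abundance": abund,
        "evidence": ev,
    }


@pytest.fixture()
def toy_path_matrix():
    """3-gene path A-B-C with uniform weights: the hand-checkable chain."""
    import numpy as np
    from scipy import sparse

    p = sparse.csr_matrix(np.array([
        [0.0, 1.0, 0.0],
        [0.5, 0.0, 0.5],
        [0.0, 1.0, 0.0],
    ]))
    return it.TissueTransitionMatrix(tissue="toy", genes=("A", "B", "C"), matrix=p)


def uniform_annotations(genes, domain="cytosol", level="medium", tissues=("t1", "t2")):
    """Identical localization and abundance for every gene (uniform-walk limit)."""
    loc = it.LocalizationMap(
        domains={g: frozenset((domain,)) for g in genes},
        vocabulary=(domain,),
    )
    abund = it.AbundanceMatrix(
        levels=pd.DataFrame(level, index=list(genes), columns=list(tissues)),
    )
    return loc, abund
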