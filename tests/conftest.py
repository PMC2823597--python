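import pytest

import mirnaprep as mp

SMALL_SPEC = ((3, 2), (2, 3), (3, 4), (1, 1))  # 9 genes, 16 features each


@pytest.fixture(scope="session")
def small_experiment():
    """Tiny 2-group x 2-array experiment for fast unit tests."""
    cfg = mp.SimulationConfig(
        n_arrays_per_group=2, design_spec=SMALL_SPEC, seed=7
    )
    tables, truth = mp.simulate_experiment(cfg)
    design = mp.infer_design(tables)
    return tables, truth, design


@pytest.fixture(scope="session")
def default_experiment():
    """One full v2.0-layout experiment (799 genes, 2 groups x 4 arrays)."""
    tables, truth = mp.simulate_experiment(mp.SimulationConfig(seed=11))
    design = mp.infer_design(tables)
    return tables, truth, design
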