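import pytest

import trmbdyn as td


@pytest.fixture(scope="session")
def binding():
    """Default simulated TF-binding curve (bound pre, dissociating at t=0)."""
    return td.simulate_binding(td.BindingParams())


@pytest.fixture(scope="session")
def noiseless_panel():
    """Small noise-free two-strain panel for exactness checks."""
    cfg = td.PanelConfig(n_activated_direct=8, n_repressed_direct=8,
                         n_ffl_target=4, n_independent_impulse=4,
                         n_no_change=2, cv=0.0, seed=0)
    return td.simulate_panel(cfg)


@pytest.fixture(scope="session")
def default_panel():
    """Full default panel (100 genes, 10% noise, 3 replicates)."""
    return td.simulate_panel(td.PanelConfig(seed=0))
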