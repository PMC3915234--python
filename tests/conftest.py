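import numpy as np
import pandas as pd
import pytest

from methylsmoke.simulate import (CohortConfig, config_with_panel,
                                  generate_reference_panel, simulate_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config cohort, shared across tests."""
    cfg = CohortConfig(seed=7)
    beta, sheet, detp, truth = simulate_cohort(cfg)
    return cfg, beta, sheet, detp, truth


@pytest.fixture(scope="session")
def panel_cohort():
    """A cohort whose signal CpGs realise a 183-CpG reference panel."""
    base = CohortConfig(seed=21)
    panel = generate_reference_panel(base, seed=11)
    cfg = config_with_panel(base, panel)
    beta, sheet, detp, truth = simulate_cohort(cfg)
    return panel, cfg, beta, sheet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_sheet():
    """Minimal two-ethnicity never/current sheet for single-CpG tests."""
    n = 40
    return pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "smoking_status": ["never"] * 25 + ["current"] * 15,
        "ethnicity": (["European", "SouthAsian"] * 20),
    })
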