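import numpy as np
import pandas as pd
import pytest

import sigbridge as sb


@pytest.fixture(scope="session")
def small_cohort() -> sb.PairedCohort:
    """Compact paired cohort reused by read-only tests."""
    cfg = sb.CohortConfig(n_patients=40, n_wts_genes=600, n_panel_genes=100,
                          n_hkg=10, seed=11)
    return sb.simulate_cohort(cfg)


@pytest.fixture()
def tiny_counts() -> pd.DataFrame:
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(30)]
    return pd.DataFrame(rng.integers(1, 5000, (30, 6)), index=genes,
                        columns=[f"s{j}" for j in range(6)])
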