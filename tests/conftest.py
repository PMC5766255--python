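import numpy as np
import pandas as pd
import pytest

from panbimodal.synthdata import SwitchSpec, simulate_multilayer


@pytest.fixture(scope="session")
def small_dataset():
    """60-cell, 2-tissue dataset with one well-separated switch and noise."""
    return simulate_multilayer(
        n_cells=60,
        tissues=[("lung", 30), ("breast", 30)],
        switches=[SwitchSpec(id="sw1", delta_mu=6.0, pi_high=0.5)],
        n_unimodal=3,
        missing_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def fitted_switch():
    """A converged two-component fit on well-separated data (n=500)."""
    from panbimodal.bimodal import fit_gmm2

    rng = np.random.default_rng(7)
    x = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1, 250)])
    return fit_gmm2(pd.Series(x), n_restarts=5, seed=7, analyte_id="sep")
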