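import warnings

import numpy as np
import pandas as pd
import pytest

from phskit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-participant synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_participants=250, seed=7))


@pytest.fixture(scope="session")
def lmm_data_factory():
    """Generator of random-intercept longitudinal datasets with known slope terms."""

    def make(n, seed, beta1=0.0, visits=4, interval=1.5, sigma=0.5, tau=0.5,
             extra_covariates=(), outcome="y"):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            phs = rng.normal()
            u = rng.normal(0.0, tau)
            extras = {c: rng.normal() for c in extra_covariates}
            for k in range(visits):
                t = interval * k
                y = 1.0 + u + beta1 * phs * t + rng.normal(0.0, sigma)
                rows.append({"participant_id": f"P{i:05d}", "time": t, "phs": phs,
                             outcome: y, **extras})
        return pd.DataFrame(rows)

    return make


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*convergence.*", category=UserWarning)
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield
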