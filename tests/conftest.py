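import numpy as np
import pandas as pd
import pytest

import survgxe as sg


def make_survival_frame(n, rng, betas=None, censor_scale=2.0):
    """Small right-censored dataset with three covariates for engine tests."""
    betas = betas if betas is not None else {"x1": 0.5, "x2": -0.3, "x3": 0.0}
    df = pd.DataFrame({
        "x1": rng.standard_normal(n),
        "x2": rng.integers(0, 2, n).astype(float),
        "x3": rng.standard_normal(n),
    })
    eta = sum(b * df[k] for k, b in betas.items())
    t = rng.exponential(np.exp(-eta))
    c = rng.exponential(censor_scale, n)
    df["time_years"] = np.minimum(t, c)
    df["event_dementia"] = (t <= c).astype(int)
    return df


@pytest.fixture(scope="session")
def small_sim():
    """Moderate synthetic dataset shared across read-only tests."""
    spec = sg.SimulationSpec(n_samples=800, n_variants=60, seed=5,
                             baseline_hazard_rate=0.02)
    genos = sg.simulate_genotypes(spec)
    cohort = sg.simulate_cohort(spec, genos)
    return spec, genos, cohort
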