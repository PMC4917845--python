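import numpy as np
import pytest

import twinace as t


def truth_from_props(h2_m, c2_m, h2_f, c2_f, sd=4.3, r_gos=0.5, **means):
    """SexLimParams with paths set from standardized proportions and a total SD."""
    v = sd * sd
    return t.SexLimParams(
        a_m=np.sqrt(h2_m * v),
        c_m=np.sqrt(c2_m * v),
        e_m=np.sqrt((1.0 - h2_m - c2_m) * v),
        a_f=np.sqrt(h2_f * v),
        c_f=np.sqrt(c2_f * v),
        e_f=np.sqrt((1.0 - h2_f - c2_f) * v),
        r_gos=r_gos,
        **means,
    )


@pytest.fixture(scope="session")
def asym_truth():
    """Sex-asymmetric generating parameters used across estimation tests."""
    return t.SexLimParams(
        a_m=2.0, c_m=1.5, e_m=1.0, a_f=1.8, c_f=1.6, e_f=0.9,
        r_gos=0.4, mu_mzm=0.3, mu_dzm=0.5, mu_mzf=-0.2, mu_dzf=0.1,
    )


@pytest.fixture(scope="session")
def asym_pairs(asym_truth):
    counts = {g: 4000 for g in t.GROUPS}
    return t.simulate_pairs_at_age(counts, asym_truth, seed=101)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated measurement table (one region)."""
    cfg = t.GeneratorConfig(
        seed=42,
        regions=[t.RegionSpec("Europe", n_families=3000, n_cohorts=3)],
    )
    return t.simulate_cohort(cfg)
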