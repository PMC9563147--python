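import numpy as np
import pandas as pd
import pytest

from tcistate import NormalReference, SimulationConfig, call_degs, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort with clean structure for unit tests."""
    cfg = SimulationConfig(
        n_tumors=150, n_drivers=6, n_passenger_sgas=10,
        n_target_degs_per_driver=8, n_noise_genes=30,
        sga_freq_range=(0.25, 0.35), crosstalk_rate=0.1, effect_size=3.0,
        n_subtypes=2, survival_scale_per_subtype=(400.0, 900.0), seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_deg(small_cohort):
    ref = NormalReference.from_normal_matrix(small_cohort.normals)
    return call_degs(small_cohort.expression, ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_binary_cohort(rng, n_tumors=40, n_sga=6, n_deg=8, p_sga=0.4, p_deg=0.3):
    """Unstructured binary matrices for arithmetic/normalisation checks."""
    tumors = [f"T{i}" for i in range(n_tumors)]
    sga = pd.DataFrame(rng.random((n_tumors, n_sga)) < p_sga,
                       index=tumors, columns=[f"S{j}" for j in range(n_sga)]).astype(int)
    deg = pd.DataFrame(rng.random((n_tumors, n_deg)) < p_deg,
                       index=tumors, columns=[f"E{j}" for j in range(n_deg)]).astype(int)
    return sga, deg
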