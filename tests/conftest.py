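import numpy as np
import pytest

import bcellkin as bk


@pytest.fixture(scope="session")
def control_params() -> bk.KineticParameters:
    return bk.table1_parameters("control")


@pytest.fixture(scope="session")
def depleted_params() -> bk.KineticParameters:
    return bk.table1_parameters("depleted")


@pytest.fixture(scope="session")
def designs() -> dict[str, bk.ExperimentDesign]:
    return bk.default_designs()


@pytest.fixture(scope="session")
def control_trajectory(control_params, designs) -> bk.LabelingTrajectory:
    return bk.simulate_experiment(control_params, designs["control"])


@pytest.fixture(scope="session")
def depleted_trajectory(depleted_params, designs) -> bk.LabelingTrajectory:
    return bk.simulate_experiment(depleted_params, designs["depleted"])


@pytest.fixture(scope="session")
def small_cohort(control_params, depleted_params, designs):
    """Deterministic synthetic cohort at the bundled best fits."""
    spec = bk.CohortSpec(
        params={"control": control_params, "depleted": depleted_params},
        designs=designs,
        seed=0,
    )
    return bk.generate_cohort(spec)


def random_params(rng: np.random.Generator) -> bk.KineticParameters:
    """A random plausible parameter set (used by property-style tests)."""
    d = {
        "S": rng.uniform(1e4, 1e6),
        "gamma": rng.uniform(0.05, 0.5),
        "K": rng.uniform(1e6, 1e8),
        "delta_oe": rng.uniform(0.1, 0.7),
        "delta_r": rng.uniform(0.0, 0.1),
        "mu_i": rng.uniform(0.01, 0.6),
        "delta_i_t": rng.uniform(0.05, 0.8),
        "delta_i_re": rng.uniform(0.05, 0.3),
        "mu_re": rng.uniform(0.001, 0.06),
        "phi_BM": rng.uniform(0.3, 2.0),
        "mu_t": rng.uniform(0.01, 0.08),
        "delta_t": rng.uniform(0.005, 0.05),
        "phi_s": rng.uniform(0.005, 0.05),
        "eps_spl": rng.uniform(0.005, 0.03),
    }
    return bk.KineticParameters.from_dict(d)
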