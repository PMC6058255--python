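import numpy as np
import pytest

import pdcascade as pc


@pytest.fixture(scope="session")
def ref_params() -> pc.PDParameters:
    return pc.baicalein_reference_params()


@pytest.fixture(scope="session")
def design() -> pc.StudyDesign:
    return pc.default_design()


@pytest.fixture(scope="session")
def prop_error() -> pc.ErrorModel:
    return pc.ErrorModel(kind="proportional", sigma_prop=0.10)


@pytest.fixture(scope="session")
def noisy_dataset(ref_params, design, prop_error):
    return pc.generate_dataset(ref_params, design, prop_error, seed=2024)


@pytest.fixture(scope="session")
def noisy_fit(noisy_dataset, design, ref_params):
    """One shared pooled-ML fit of a well-specified noisy dataset."""
    return pc.fit(noisy_dataset, design, init=ref_params, n_starts=2, seed=7)


def random_valid_params(rng: np.random.Generator) -> pc.PDParameters:
    """Random parameter set around the reference values, valid at 40 μM."""
    ref = pc.baicalein_reference_params()
    scale = lambda v: v * rng.uniform(0.2, 5.0)  # noqa: E731
    return pc.PDParameters(
        alpha=rng.uniform(0.0, 0.95 / np.log(40.0)),
        k_in_tnf=scale(ref.k_in_tnf),
        k_out_tnf=scale(ref.k_out_tnf),
        k_in_il6=scale(ref.k_in_il6),
        k_out_il6=scale(ref.k_out_il6),
        tau1=rng.uniform(0.0, 4.0),
        k_in_inos=scale(ref.k_in_inos),
        k_out_inos=0.0,
        tau2=rng.uniform(0.0, 4.0),
        k_in_no=scale(ref.k_in_no),
        k_out_no=0.0,
        delta=rng.uniform(0.5, 2.0),
        tnf0=rng.uniform(10.0, 200.0),
        il6_0=rng.uniform(5.0, 100.0),
        inos0=1.0,
        no0=rng.uniform(0.5, 2.0),
    )
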