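import numpy as np
import pytest

from hemuq import (
    CouetteDesign,
    HemolysisModel,
    NoiseSpec,
    PriorSpec,
    REFERENCE_PARAMS,
    SamplerConfig,
    default_condition_specs,
    generate_couette_dataset,
    generate_stress_volume_field,
)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """108-record noise-free Couette dataset at the reference parameters."""
    return generate_couette_dataset(
        CouetteDesign(noise=NoiseSpec(kind="none"), seed=1)
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default noisy Couette dataset (student-t scatter, sigma 0.1)."""
    return generate_couette_dataset(CouetteDesign(seed=7))


@pytest.fixture(scope="session")
def fixedc_results(noisy_dataset):
    """Quick fixed-C posterior fit shared across tests."""
    model = HemolysisModel(
        noisy_dataset, priors=PriorSpec().fix_c(REFERENCE_PARAMS.c_coeff)
    )
    return model.fit(SamplerConfig.quick(seed=2))


@pytest.fixture(scope="session")
def posterior_fits(fixedc_results):
    """Truncated log-normal fits of the alpha/beta marginals."""
    return {
        name: fixedc_results.fit_truncated_lognormal(name)
        for name in ("alpha", "beta")
    }


@pytest.fixture(scope="session")
def condition_fields():
    """The six default synthetic device flow conditions."""
    return {
        spec.condition_label: generate_stress_volume_field(spec)
        for spec in default_condition_specs(seed=0)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
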