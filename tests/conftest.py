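import numpy as np
import pytest

from cellscatter import (
    ScatteringProfile,
    default_saxs_truth,
    default_waxs_truth,
    generate_saxs_profile,
    generate_waxs_profile,
)


@pytest.fixture(scope="session")
def waxs_truth_noiseless():
    return default_waxs_truth(ci=0.55, noise_fraction=0.0)


@pytest.fixture(scope="session")
def waxs_profile_noiseless(waxs_truth_noiseless):
    profile, _ = generate_waxs_profile(waxs_truth_noiseless, seed=0)
    return profile


@pytest.fixture(scope="session")
def saxs_truth_noiseless():
    return default_saxs_truth(d_cc=40.0, noise_fraction=0.0)


@pytest.fixture(scope="session")
def saxs_profile_noiseless(saxs_truth_noiseless):
    profile, _ = generate_saxs_profile(saxs_truth_noiseless, seed=0)
    return profile


@pytest.fixture()
def simple_profile():
    q = np.linspace(0.05, 0.5, 50)
    return ScatteringProfile(
        q=q,
        intensity=np.exp(-q),
        sigma=np.full_like(q, 0.01),
        modality="SAXS",
        sample_id="s1",
        condition="reference",
        replicate=1,
        normalized=True,
    )
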