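import numpy as np
import pandas as pd
import pytest

from castrop.model_eye import DEFAULT_EYE, CastropConstants
from castrop.simulate import GeneratorSpec, generate_dataset

#: Population-mean eye used throughout the tests (mm / dpt).
MEAN_EYE = {"AL": 23.497, "ACD": 3.099, "LT": 4.608, "RCA": 7.668}

#: Same eye as positional (al, acd, lt, rca) arguments for the optics API.
MEAN_ARGS = (MEAN_EYE["AL"], MEAN_EYE["ACD"], MEAN_EYE["LT"], MEAN_EYE["RCA"])

#: Constant triplet typical of a one-piece acrylic lens.
STUDY_CONSTANTS = CastropConstants(0.424, -0.312, 0.077)


@pytest.fixture
def eye():
    return DEFAULT_EYE


@pytest.fixture
def mean_eye():
    return dict(MEAN_EYE)


@pytest.fixture
def study_constants():
    return STUDY_CONSTANTS


@pytest.fixture(scope="session")
def noisy_dataset():
    """Moderate synthetic cohort with realistic noise and quantization."""
    return generate_dataset(GeneratorSpec(n=400, seed=20240))


@pytest.fixture(scope="session")
def clean_dataset():
    """Self-consistent cohort: no noise, no power rounding, no quantization."""
    spec = GeneratorSpec(
        n=400,
        seed=77,
        refraction_noise_sd=0.0,
        iol_power_step=0.0,
        quantize_refraction=False,
    )
    return generate_dataset(spec)


def random_valid_records(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Uniformly scattered but physically plausible biometry records."""
    return pd.DataFrame(
        {
            "AL": rng.uniform(20.5, 29.0, n),
            "ACD": rng.uniform(2.2, 4.2, n),
            "LT": rng.uniform(3.4, 5.7, n),
            "RCA": rng.uniform(6.8, 8.6, n),
        }
    )
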