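import numpy as np
import pytest

from drumalg import (
    ForcingProtocol,
    build_variant,
    reference_parameters,
)
from drumalg.synthetic import (
    DAY_NIGHT_INITIAL,
    SyntheticProtocolSpec,
    default_sampling_times,
    generate_calibration_dataset,
)

ALL_VARIANTS = ("w/oEx", "ExCARB", "ExG6P", "ExPEP", "ExGAP")


@pytest.fixture(scope="session")
def excarb():
    return build_variant("ExCARB")


@pytest.fixture(scope="session")
def woex():
    return build_variant("w/oEx")


@pytest.fixture(scope="session")
def excarb_params():
    return reference_parameters("ExCARB")


@pytest.fixture(scope="session")
def day_night_protocol():
    return ForcingProtocol.day_night_starvation()


@pytest.fixture(scope="session")
def initial_state():
    return DAY_NIGHT_INITIAL


@pytest.fixture(scope="session")
def tiny_dataset():
    """Noiseless 2-day ExCARB dataset with sparse sampling, for fast fits."""
    spec = SyntheticProtocolSpec(
        experiment="day_night_starvation",
        variant="ExCARB",
        noise_cv=0.0,
        sampling_times=default_sampling_times(n_days=2, every_h=6.0),
        seed=0,
        warmup_h=48.0,
    )
    return spec, generate_calibration_dataset(spec)
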