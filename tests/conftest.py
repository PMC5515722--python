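import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import alphadose as ad

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

LN2 = math.log(2.0)


@pytest.fixture(scope="session")
def ac225():
    return ad.get_radionuclide("Ac-225")


@pytest.fixture(scope="session")
def bi213():
    return ad.get_radionuclide("Bi-213")


@pytest.fixture(scope="session")
def pb212():
    return ad.get_radionuclide("Pb-212")


@pytest.fixture(scope="session")
def at211():
    return ad.get_radionuclide("At-211")


@pytest.fixture
def ac_blood_model():
    """Biexponential blood clearance, 63%/6 h + 37%/19 h at 30 %IA/g."""
    return ad.MultiExponentialModel(
        terms=((0.63 * 30.0, LN2 / 6.0), (0.37 * 30.0, LN2 / 19.0)),
        organ_label="blood",
    )


@pytest.fixture
def blood_truth():
    return ad.blood_truth_from_summary((63.0, 37.0), (6.0, 19.0), c0=30.0)


@pytest.fixture
def small_dataset():
    """Noise-free three-organ dataset on the default schedule."""
    lib = [m for m in ad.default_organ_library(noise_cv=0.0)
           if m.organ_label in ("blood", "kidneys", "tumor")]
    return ad.generate_biodistribution(lib, n_per_time=3, seed=7)


def two_point_curve(t1, c1, t2, c2, label="organ"):
    return ad.TimeActivityCurve(label, np.array([t1, t2]), np.array([c1, c2]))
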