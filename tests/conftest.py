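import numpy as np
import pytest

from fdgclamp import io as cio
from fdgclamp.cohort import LR_DEFAULT, HR_DEFAULT, simulate_cohort
from fdgclamp.synthetic import InputModelParams, input_function_from_model


@pytest.fixture(scope="session")
def feng_params():
    return InputModelParams()


@pytest.fixture(scope="session")
def feng_input(feng_params):
    """Default bolus model densely sampled into an input function."""
    return input_function_from_model(feng_params, t_end_min=125.0)


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """Full-size default two-group cohort (22 LR / 19 HR), written to disk."""
    cohort = simulate_cohort(seed=7)
    out = tmp_path_factory.mktemp("cohort") / "default"
    cio.write_cohort(cohort, out)
    return cohort, out


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 3+3-subject cohort for fast pipeline plumbing tests."""
    lr = LR_DEFAULT.model_copy(update={"n": 3, "n_missing_urine": 1})
    hr = HR_DEFAULT.model_copy(update={"n": 3})
    cohort = simulate_cohort(lr, hr, seed=3)
    out = tmp_path_factory.mktemp("cohort_small") / "c"
    cio.write_cohort(cohort, out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
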