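import numpy as np
import pytest

from alctraj.synthetic import default_config, generate_cohort, truth_lcmm_fit
from alctraj.lcmm import TrajectoryData, TrajectorySpec, fit_single_start, posterior_probs


@pytest.fixture(scope="session")
def small_cohort():
    """Default-config cohort at n=600, with its ground truth."""
    cfg = default_config(n_subjects=600, seed=11)
    intakes, subjects, truth = generate_cohort(cfg)
    return cfg, intakes, subjects, truth


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """A 4-class fit of the small cohort started at the generator truth."""
    cfg, intakes, subjects, truth = small_cohort
    data = TrajectoryData.from_frame(intakes)
    fit = fit_single_start(data, TrajectorySpec(4), truth_lcmm_fit(cfg))
    post = posterior_probs(fit, data)
    return cfg, data, fit, post, truth
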