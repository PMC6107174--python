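import numpy as np
import pytest

from swaymf import CascadeSpec, CohortSpec, ScalingConfig, binomial_cascade


@pytest.fixture(scope="session")
def cascade_q25():
    """Random binomial cascade with p = 0.25, k = 12 (4096 samples)."""
    return binomial_cascade(CascadeSpec(p=0.25, k=12, seed=11))


@pytest.fixture(scope="session")
def small_cohort_spec():
    """A reduced cohort for pipeline tests: 3 subjects, 4012 samples."""
    return CohortSpec(n_subjects=3, series_length=4012, seed=5)


@pytest.fixture()
def fast_cfg():
    """Scaling config with a short q sweep for cheap estimates."""
    return ScalingConfig(q_values=np.arange(-20.0, 21.0))
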