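import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lamodc import (AcquisitionModel, DecoderConfig, RunDesign, build_session_samples,
                    highpass_filter, make_cortex_patch, simulate_odc_pattern,
                    simulate_run)
from lamodc.pipeline import simulate_session

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.filter_too_much])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def patch():
    """Small patch with all five visual regions (48x48 vertices, 0.3 mm)."""
    return make_cortex_patch(48, 48, spacing_mm=0.3, thickness_mm=2.0)


@pytest.fixture(scope="session")
def cmap(patch):
    return simulate_odc_pattern(patch, period_mm=1.0, seed=11)


@pytest.fixture(scope="session")
def design():
    return RunDesign()


def make_session_samples(patch, cmap, model=None, n_runs=4, seed=0, regions="V1",
                         highpass=True):
    """Simulate, filter and stack a small session for decoding tests."""
    model = model or AcquisitionModel.ge_bold()
    runs, designs = simulate_session(patch, cmap, model, RunDesign(), n_runs, seed)
    if highpass:
        runs = [highpass_filter(r, 1.0 / 270.0) for r in runs]
    return build_session_samples(runs, designs, patch, regions=regions)


@pytest.fixture(scope="session")
def ge_samples(patch, cmap):
    return make_session_samples(patch, cmap, n_runs=4, seed=5)
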