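import numpy as np
import pytest

from linefrap import AcquisitionParams, Kymograph


@pytest.fixture
def line_scan_params():
    """The line-scan geometry used throughout: 0.207 µm pixels, 1.256 ms
    lines, 10/42/948 pre/during/post schedule."""
    return AcquisitionParams()


@pytest.fixture
def short_params():
    """A short schedule for fast synthetic fixtures."""
    return AcquisitionParams(
        n_prebleach=10, n_bleach=0, n_postbleach=200, bleach_center=24
    )


def make_step_kymograph(
    params,
    pre_value=1000.0,
    post_value=400.0,
    n_pixels=48,
    background=0.0,
):
    """Noiseless kymograph: uniform prebleach plateau, uniform post-bleach
    value (instantaneous bleach, no recovery)."""
    n = params.n_lines
    arr = np.full((n, n_pixels), float(pre_value))
    first_post = params.n_prebleach + params.n_bleach
    arr[first_post:] = post_value
    if params.n_bleach:
        arr[params.n_prebleach : first_post] = post_value
    return Kymograph(intensities=arr, params=params, background=background)


@pytest.fixture
def step_kymograph(short_params):
    return make_step_kymograph(short_params)
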