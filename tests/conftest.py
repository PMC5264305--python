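"""Shared fixtures: small phantoms sized for fast, full-chain testing."""

import numpy as np
import pytest

from myodti.phantom import PhantomParams, generate_phantom
from myodti.pipeline import AnalysisOptions, analyze_phantom

# 32 mm in-plane field of view, 7 mm wall, 12 mm of long axis: small enough for
# seconds-scale tensor fits while keeping ~4 included short-axis slabs
SMALL_KW = dict(
    grid_shape=(64, 64, 24),
    endo_radius_mm=8.0,
    epi_radius_mm=15.0,
    voxel_size_mm=(0.5, 0.5, 0.5),
)


@pytest.fixture(scope="session")
def small_noiseless_infarcted():
    return generate_phantom(PhantomParams(snr=np.inf, seed=11, **SMALL_KW))


@pytest.fixture(scope="session")
def small_noiseless_control():
    return generate_phantom(PhantomParams(snr=np.inf, seed=11, **SMALL_KW).control())


@pytest.fixture(scope="session")
def small_noisy_infarcted():
    return generate_phantom(PhantomParams(snr=120.0, seed=11, **SMALL_KW))


@pytest.fixture(scope="session")
def analysis_noiseless_control(small_noiseless_control):
    return analyze_phantom(
        small_noiseless_control, AnalysisOptions(heart_type="control"), heart_id="ctrl"
    )


@pytest.fixture(scope="session")
def analysis_noiseless_infarcted(small_noiseless_infarcted):
    return analyze_phantom(small_noiseless_infarcted, heart_id="inf")


@pytest.fixture(scope="session")
def analysis_noisy_infarcted(small_noisy_infarcted):
    return analyze_phantom(small_noisy_infarcted, heart_id="inf-noisy")
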