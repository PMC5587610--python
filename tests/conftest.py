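import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import retoxim as rx
from retoxim.physiology import (
    DEFAULT_CALIBRATIONS,
    DEFAULT_DISSOCIATION_CURVE,
    DEFAULT_DK_ML_O2_PER_CM_S_MMHG,
)

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

DK_PER_MIN = DEFAULT_DK_ML_O2_PER_CM_S_MMHG * 60.0


@pytest.fixture(scope="session")
def g2():
    """G2 (tissue) calibration, accessed directly to avoid the default warning."""
    return DEFAULT_CALIBRATIONS["G2"]


@pytest.fixture(scope="session")
def r0():
    return DEFAULT_CALIBRATIONS["R0"]


@pytest.fixture(scope="session")
def curve():
    return DEFAULT_DISSOCIATION_CURVE


@pytest.fixture(scope="session")
def scene_clean():
    """Noise-free default scene: arteries 41 mmHg, vein 25, inner tissue 23,
    outer profile built with QO2 = 0.57 mL O2/100g/min."""
    return rx.build_scene(noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def acq():
    return rx.AcquisitionSettings()


@pytest.fixture(scope="session")
def stacks_clean(scene_clean, acq):
    return rx.render_phase_stacks(scene_clean, acq)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, scene_clean, stacks_clean, acq):
    d = tmp_path_factory.mktemp("fixture")
    tissue, vascular = stacks_clean
    rx.write_fixture(scene_clean, tissue, vascular, d, acq)
    return d


@pytest.fixture(scope="session")
def tissue_po2_mean(stacks_clean, g2):
    """Replicate-mean tissue PO2 map from the noise-free scene."""
    tissue, _ = stacks_clean
    maps = [rx.po2_map(rx.estimate_lifetime_map(s), g2) for s in tissue]
    return rx.average_replicate_maps(maps)


def homodyne_intensity(phases_deg, tau_s, freq_hz, amplitude, mod_depth):
    """Independent closed-form homodyne model for oracle comparisons."""
    omega = 2.0 * np.pi * freq_hz
    wt = omega * tau_s
    phi = np.arctan(wt)
    M = 1.0 / np.sqrt(1.0 + wt**2)
    th = np.deg2rad(np.asarray(phases_deg, dtype=float))
    return amplitude * (1.0 + mod_depth * M * np.cos(th - phi))
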