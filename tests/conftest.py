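import numpy as np
import pytest

from pulmoflow import synth


@pytest.fixture(scope="session")
def arterial():
    """Reference arterial curve: 106 ml stroke volume at 61 bpm, 35 frames."""
    return synth.make_arterial_waveform(rr_interval=984.0, stroke_volume=106.0, n_frames=35, seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless cohort shared by conservation / round-trip tests."""
    return synth.generate_cohort(n_subjects=4, seed=42, flow_noise_sd=0.0)


@pytest.fixture(scope="session")
def rendered(arterial):
    """Noiseless rendered MPA plane with a known eddy-current surface."""
    return synth.render_pc_series(
        arterial,
        vessel_area=700.0,
        venc=175.0,
        pixel_spacing=1.4,
        noise_sd=0.0,
        eddy_coeffs=[1.0, 0.02, 0.01, -0.0005, 0.0, 0.0],
        seed=7,
    )
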