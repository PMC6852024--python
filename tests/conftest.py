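import numpy as np
import pytest

from pcflow import (default_phantom_spec, fit_shape_model,
                    generate_phantom_series, generate_training_set)
from pcflow._geometry import circle_polygon


@pytest.fixture(scope="session")
def default_phantom():
    """Study-default pulsatile phantom (noise, contrast drop, neighbour)."""
    spec = default_phantom_spec(seed=1)
    series, truth, true_flow, true_volume = generate_phantom_series(spec)
    return spec, series, truth, true_flow, true_volume


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, plane-free phantom for discretization-only checks."""
    spec = default_phantom_spec(seed=0, noise_sigma_magnitude=0.0,
                                noise_sigma_phase=0.0,
                                background_plane=(0.0, 0.0, 0.0))
    series, truth, true_flow, true_volume = generate_phantom_series(spec)
    return spec, series, truth, true_flow, true_volume


@pytest.fixture(scope="session")
def aorta_model():
    """Shape model trained on a synthetic reference cohort."""
    return fit_shape_model(generate_training_set(12, seed=2025),
                           vessel_label="aorta")


@pytest.fixture()
def circle():
    return circle_polygon(20.0, 22.0, 10.0, n=64)
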