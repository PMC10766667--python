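import numpy as np
import pytest

from tomoelast import (ComplexWaveField, MaterialProps, WaveSimConfig,
                       homogeneous_phantom, MOUSE_FREQUENCIES)


def plane_wave(shape, spacing_mm, k_rad_m, angle_rad=0.0, decay_rad_m=0.0,
               frequency=1000.0):
    """Analytic 2D plane wave exp(i k n.x - gamma n.x) as a ComplexWaveField."""
    axes = [np.arange(n) * s * 1e-3 for n, s in zip(shape, spacing_mm)]
    y, x = np.meshgrid(*axes, indexing="ij")
    n0, n1 = np.cos(angle_rad), np.sin(angle_rad)
    t = n0 * y + n1 * x
    u = np.exp(1j * k_rad_m * t - decay_rad_m * t)
    return ComplexWaveField(u, frequency, spacing_mm)


def on_grid_wavenumber(shape, spacing_mm, cycles, axis=0):
    """Wavenumber (rad/m) of a wave with an integer number of cycles across
    the grid along one axis, i.e. exactly periodic for the FFT."""
    extent_m = shape[axis] * spacing_mm[axis] * 1e-3
    return 2.0 * np.pi * cycles / extent_m


@pytest.fixture
def elastic_material():
    return MaterialProps(4000.0)  # SWS exactly 2.0 m/s


@pytest.fixture
def viscous_material():
    return MaterialProps(3000.0, 0.6)


@pytest.fixture
def four_direction_cfg():
    angles = np.deg2rad((10.0, 100.0, 205.0, 295.0))
    return WaveSimConfig(frequencies=MOUSE_FREQUENCIES,
                         directions=[(np.cos(a), np.sin(a)) for a in angles])


@pytest.fixture
def elastic_fields(elastic_material, four_direction_cfg):
    from tomoelast import simulate_multifrequency

    phantom = homogeneous_phantom(elastic_material)
    return phantom, simulate_multifrequency(phantom, four_direction_cfg)
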