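"""Wave-image preprocessing before inversion.

The mouse chain is: Gaussian smoothing (sigma 0.15 mm) -> 2D first-order
Butterworth low-pass (threshold 600 1/m) -> decomposition into 8 in-plane
propagation directions -> phase-gradient wavenumber estimation.  The human
chain replaces the Gaussian by a 200 1/m Butterworth, removes compressional
content with a 3D curl operator, and uses 20 propagation directions.

All operations are linear in the field; the directional windows form an
exact partition of unity so the decomposed components sum back to the
input.  The Butterworth "threshold" is interpreted as the radial cutoff
spatial frequency in cycles/m (600 1/m corresponds to a 1.67 mm
wavelength).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .params import ComplexWaveField, ParamMap


@dataclass
class FilterConfig:
    """Preprocessing parameters for one reconstruction chain."""

    gauss_sigma_mm: float = 0.15
    butterworth_cutoff_inv_m: float = 600.0
    butterworth_order: int = 1
    n_directions: int = 8
    dims: int = 2

    def __post_init__(self):
        if self.butterworth_cutoff_inv_m <= 0:
            raise ValueError("butterworth cutoff must be > 0")
        if self.butterworth_order < 1:
            raise ValueError("butterworth order must be >= 1")
        if self.n_directions < 2:
            raise ValueError("n_directions must be >= 2")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")


MOUSE_FILTERS = FilterConfig(0.15, 600.0, 1, 8, 2)
HUMAN_FILTERS = FilterConfig(0.0, 200.0, 1, 20, 3)


# --------------------------------------------------------------------------
# smoothing and spectral low-pass
# --------------------------------------------------------------------------

def gaussian_smooth(field: ComplexWaveField, sigma_mm: float) -> ComplexWaveField:
    """Mask-aware Gaussian smoothing of the complex field.

    Normalised convolution: smooth(u * m) / smooth(m) over the valid mask, so
    invalid voxels neither leak into nor dilute their neighbours.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return field.with_values(field.values.copy())
    sigmas = [sigma_mm / s for s in field.spacing]  # voxels per axis
    m = field.mask.astype(float)
    u = np.where(field.mask, field.values, 0.0)
    num_r = gaussian_filter(u.real, sigmas)
    num_i = gaussian_filter(u.imag, sigmas)
    den = gaussian_filter(m, sigmas)
    out = np.zeros_like(field.values)
    ok = den > 1e-12
    out[ok] = (num_r[ok] + 1j * num_i[ok]) / den[ok]
    out = np.where(field.mask, out, 0.0)
    return field.with_values(out)


def _spatial_frequencies(shape, spacing_m) -> List[np.ndarray]:
    """Per-axis FFT sample frequencies in cycles/m."""
    return [np.fft.fftfreq(n, d=h) for n, h in zip(shape, spacing_m)]


def butterworth_lowpass(field: ComplexWaveField, cutoff_inv_m: float,
                        order: int = 1) -> ComplexWaveField:
    """Radial Butterworth low-pass in the spatial-frequency domain.

    H(xi) = 1 / sqrt(1 + (|xi| / xi_c)^(2*order)) with |xi| the radial
    spatial frequency in cycles/m; zero-phase and purely radial.
    """
    if cutoff_inv_m <= 0:
        raise ValueError("cutoff must be positive")
    freqs = _spatial_frequencies(field.shape, field.spacing_m)
    grids = np.meshgrid(*freqs, indexing="ij")
    radial = np.sqrt(sum(g ** 2 for g in grids))
    h = 1.0 / np.sqrt(1.0 + (radial / cutoff_inv_m) ** (2 * order))
    out = np.fft.ifftn(np.fft.fftn(field.values) * h)
    return field.with_values(out)


# --------------------------------------------------------------------------
# directional decomposition
# --------------------------------------------------------------------------

def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def direction_windows_2d(shape, spacing_m, n_directions: int) -> List[np.ndarray]:
    """Raised-cosine angular windows over the signed spectral angle.

    Window d is centred at theta_d = 2*pi*d/n with half-width 2*pi/n:
    W_d = cos^2(n * delta / 4) on its support, which makes adjacent windows
    sum to cos^2 + sin^2 = 1, an exact partition of unity.  The DC sample,
    whose angle is undefined, is shared equally.
    """
    freqs = _spatial_frequencies(shape, spacing_m)
    g0, g1 = np.meshgrid(*freqs, indexing="ij")
    theta = np.arctan2(g1, g0)
    dc = (g0 == 0) & (g1 == 0)
    half_width = 2.0 * np.pi / n_directions
    windows = []
    for d in range(n_directions):
        delta = _wrap_angle(theta - 2.0 * np.pi * d / n_directions)
        w = np.where(np.abs(delta) < half_width,
                     np.cos(n_directions * delta / 4.0) ** 2, 0.0)
        w[dc] = 1.0 / n_directions
        windows.append(w)
    return windows


def fibonacci_directions(n: int) -> np.ndarray:
    """Symmetrised spherical Fibonacci direction set (n even): n/2 points on
    the upper hemisphere plus their antipodes; unit vectors, axis order
    (slice, row, column)."""
    if n % 2:
        raise ValueError("n must be even for a symmetrised set")
    m = n // 2
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(m)
    z = (i + 0.5) / m            # cos(polar) in (0, 1): upper hemisphere
    phi = 2.0 * np.pi * i / golden
    s = np.sqrt(1.0 - z ** 2)
    upper = np.stack([z, s * np.cos(phi), s * np.sin(phi)], axis=1)
    return np.concatenate([upper, -upper], axis=0)


def direction_windows_3d(shape, spacing_m, n_directions: int) -> List[np.ndarray]:
    """Partition-of-unity windows on the sphere of spectral directions.

    Raw lobes are clipped squared cosines around each direction of a
    symmetrised Fibonacci set, normalised sample-wise so the windows sum to
    one exactly.
    """
    dirs = fibonacci_directions(n_directions)
    freqs = _spatial_frequencies(shape, spacing_m)
    grids = np.stack(np.meshgrid(*freqs, indexing="ij"))
    norm = np.sqrt(np.sum(grids ** 2, axis=0))
    dc = norm == 0
    safe = np.where(dc, 1.0, norm)
    unit = grids / safe
    raw = []
    for d in dirs:
        c = np.tensordot(d, unit, axes=1)
        raw.append(np.clip(c, 0.0, None) ** 2)
    total = np.sum(raw, axis=0)
    total = np.where(total <= 0, 1.0, total)
    windows = []
    for w in raw:
        win = w / total
        win[dc] = 1.0 / n_directions
        windows.append(win)
    return windows


def directional_decompose(field: ComplexWaveField,
                          n_directions: int) -> List[ComplexWaveField]:
    """Split a field into components travelling in distinct directions.

    Spectral multiplication by angular windows; because the windows form a
    partition of unity, summing the returned components reproduces the input
    to numerical precision.
    """
    if n_directions < 2:
        raise ValueError("n_directions must be >= 2")
    if field.values.ndim == 2:
        windows = direction_windows_2d(field.shape, field.spacing_m, n_directions)
    elif field.values.ndim == 3:
        windows = direction_windows_3d(field.shape, field.spacing_m, n_directions)
    else:
        raise ValueError("directional decomposition supports 2D or 3D fields")
    spec = np.fft.fftn(field.values)
    return [field.with_values(np.fft.ifftn(spec * w)) for w in windows]


# --------------------------------------------------------------------------
# curl high-pass (human 3D chain)
# --------------------------------------------------------------------------

def curl_highpass(components: Sequence[ComplexWaveField]) -> List[ComplexWaveField]:
    """Curl of a 3-component displacement field by central differences.

    Removes compressional (curl-free) wave content; the three returned
    components are the curl vector in 1/m times the displacement unit.
    """
    if len(components) != 3:
        raise ValueError("curl requires exactly 3 vector components")
    shapes = {c.shape for c in components}
    if len(shapes) != 1:
        raise ValueError("components must share one grid")
    u = [c.values for c in components]
    h = components[0].spacing_m

    def d(a, axis):
        return np.gradient(a, h[axis], axis=axis)

    curl = [
        d(u[2], 1) - d(u[1], 2),
        d(u[0], 2) - d(u[2], 0),
        d(u[1], 0) - d(u[0], 1),
    ]
    names = ("curl0", "curl1", "curl2")
    return [
        ComplexWaveField(curl[i], components[i].frequency, components[i].spacing,
                         mask=components[i].mask, component=names[i])
        for i in range(3)
    ]


# --------------------------------------------------------------------------
# phase-gradient wavenumber estimation
# --------------------------------------------------------------------------

def _masked_gradient(u: np.ndarray, mask: np.ndarray, spacing_m) -> List[np.ndarray]:
    """Per-axis derivative: central where both neighbours valid, one-sided at
    mask borders, zero where no valid neighbour exists."""
    grads = []
    for ax, h in enumerate(spacing_m):
        up = np.roll(u, -1, axis=ax)
        um = np.roll(u, 1, axis=ax)
        mp = np.roll(mask, -1, axis=ax)
        mm = np.roll(mask, 1, axis=ax)
        # edges of the array have no wrapped neighbour
        sl_hi = [slice(None)] * u.ndim
        sl_hi[ax] = -1
        sl_lo = [slice(None)] * u.ndim
        sl_lo[ax] = 0
        mp[tuple(sl_hi)] = False
        mm[tuple(sl_lo)] = False
        g = np.zeros_like(u)
        both = mp & mm
        g[both] = (up[both] - um[both]) / (2.0 * h)
        fwd = mp & ~mm
        g[fwd] = (up[fwd] - u[fwd]) / h
        bwd = mm & ~mp
        g[bwd] = (u[bwd] - um[bwd]) / h
        grads.append(g)
    return grads


def phase_gradient_wavenumber(field: ComplexWaveField,
                              dispersion_correction: bool = True,
                              amplitude_floor_fraction: float = 0.01,
                              ) -> Tuple[ParamMap, ParamMap]:
    """Local wavenumber magnitude from the phase gradient, without unwrapping.

    Per axis, k_i = Im(conj(u) * du/dx_i) / |u|^2, which equals the true
    phase derivative without any explicit unwrapping.  With central
    differences the estimate of a plane wave is sin(k_i h)/h; when
    ``dispersion_correction`` is on, the inverse map arcsin(k_i h)/h removes
    that bias exactly for plane waves.

    Voxels whose amplitude falls below ``amplitude_floor_fraction`` of the
    95th-percentile slice amplitude are masked to prevent wavenumber blow-up
    at nodes.  Returns (wavenumber map in rad/m, amplitude map).
    """
    u = field.values
    if not np.any(u[field.mask] != 0):
        raise ValueError("field is zero everywhere on its mask")
    h = field.spacing_m
    grads = _masked_gradient(u, field.mask, h)
    absu2 = np.abs(u) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kvec = [np.imag(np.conj(u) * g) / absu2 for g in grads]
    if dispersion_correction:
        kvec = [np.arcsin(np.clip(k * hi, -1.0, 1.0)) / hi
                for k, hi in zip(kvec, h)]
    k = np.sqrt(sum(np.square(kc) for kc in kvec))

    amp = np.abs(u)
    if u.ndim == 3:
        # slice-wise floor along the first (slice) axis
        ref = np.nanpercentile(np.where(field.mask, amp, np.nan),
                               95, axis=(1, 2), keepdims=True)
    else:
        ref = np.nanpercentile(np.where(field.mask, amp, np.nan), 95)
    floor = amplitude_floor_fraction * ref
    valid = field.mask & (amp > floor) & np.isfinite(k)
    kmap = ParamMap(np.where(valid, k, np.nan), "rad/m", field.spacing, mask=valid)
    ampmap = ParamMap(np.where(field.mask, amp, np.nan), "a.u.", field.spacing,
                      mask=field.mask)
    return kmap, ampmap
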