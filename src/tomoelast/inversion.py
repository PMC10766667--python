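"""k-MDEV and MDEV inversion of preprocessed multifrequency wave fields.

k-MDEV estimates local shear wave speed from phase-gradient wavenumbers of
directionally filtered wave components: c_{f,d} = 2*pi*f / k_{f,d}, compounded
over frequencies and directions with amplitude^p weights.  MDEV performs the
algebraic Helmholtz inversion on the smoothed (not decomposed) fields,
pooling frequencies and components:

    |G*| = rho * sum omega_f^2 |u_fc| / sum |lap u_fc|
    phi  = arccos( -sum Re(conj(u_fc) lap u_fc) / sum |u_fc| |lap u_fc| )

Both are local, model-light inversions; |G*| inherits a known upward bias
from the discrete Laplacian, quantified by `laplacian_dispersion_factor` and
optionally removed with ``dispersion_correction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .params import ComplexWaveField, ParamMap
from .preproc import phase_gradient_wavenumber, _masked_gradient


@dataclass
class InversionConfig:
    density: float = 1000.0            # kg/m^3
    amplitude_weight_power: int = 2    # p in w = amplitude^p
    sws_cap: float = 10.0              # m/s; suppresses near-node divergence
    min_amplitude_fraction: float = 0.01
    dispersion_correction: bool = False  # MDEV discrete-Laplacian de-bias

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.sws_cap <= 0:
            raise ValueError("sws_cap must be > 0")


MOUSE_INVERSION = InversionConfig(sws_cap=10.0)
HUMAN_INVERSION = InversionConfig(sws_cap=5.0)


# --------------------------------------------------------------------------
# Laplacian
# --------------------------------------------------------------------------

def laplacian(values: np.ndarray, spacing_mm) -> np.ndarray:
    """Second-order central-difference Laplacian in 1/m^2 units.

    Edge-replicating boundary handling (zero curvature at the border);
    downstream statistics erode one voxel from the mask anyway.
    """
    values = np.asarray(values)
    if min(values.shape) < 3:
        raise ValueError("laplacian needs at least 3 voxels per axis")
    spacing_m = [s * 1e-3 for s in np.atleast_1d(spacing_mm)]
    if len(spacing_m) == 1:
        spacing_m = spacing_m * values.ndim
    padded = np.pad(values, 1, mode="edge")
    core = tuple(slice(1, -1) for _ in range(values.ndim))
    out = np.zeros_like(values)
    for ax, h in enumerate(spacing_m):
        up = tuple(slice(2, None) if a == ax else slice(1, -1)
                   for a in range(values.ndim))
        dn = tuple(slice(0, -2) if a == ax else slice(1, -1)
                   for a in range(values.ndim))
        out = out + (padded[up] - 2.0 * padded[core] + padded[dn]) / h ** 2
    return out


def laplacian_dispersion_factor(k_components: Sequence[float],
                                spacing_mm) -> float:
    """Ratio (true k^2) / (discrete-Laplacian k^2) for a plane wave.

    The central second difference of exp(i k x) returns
    -(2/h)^2 sin^2(k h / 2) per axis instead of -k^2, so MDEV's |G*|
    (which divides by |lap u|) is biased upward by exactly this factor.
    """
    k = np.asarray(k_components, dtype=float)
    h = np.asarray([s * 1e-3 for s in np.atleast_1d(spacing_mm)], dtype=float)
    if h.size == 1:
        h = np.repeat(h, k.size)
    k2 = float(np.sum(k ** 2))
    if k2 == 0:
        return 1.0
    disc = float(np.sum((2.0 / h * np.sin(k * h / 2.0)) ** 2))
    return k2 / disc


# --------------------------------------------------------------------------
# k-MDEV
# --------------------------------------------------------------------------

def kmdev_compound_sws(entries: Sequence[Tuple[float, ParamMap, ParamMap]],
                       cfg: InversionConfig = MOUSE_INVERSION) -> ParamMap:
    """Compound shear wave speed from per-(frequency, direction) wavenumbers.

    Parameters
    ----------
    entries : sequence of (frequency_hz, k_map, amplitude_map)
        One entry per frequency/direction pair, typically the outputs of
        `phase_gradient_wavenumber` on each directional component.
    cfg : InversionConfig

    Per entry, c = 2*pi*f / k clipped to (0, sws_cap]; the compound map is
    the amplitude^p weighted mean over entries.  Directions whose amplitude
    falls below the floor contribute zero weight; a voxel with no weight at
    all is masked.
    """
    if len(entries) == 0:
        raise ValueError("no (frequency, k, amplitude) entries given")
    shapes = {e[1].shape for e in entries} | {e[2].shape for e in entries}
    if len(shapes) != 1:
        raise ValueError("all k and amplitude maps must share one grid")
    shape = shapes.pop()
    num = np.zeros(shape)
    den = np.zeros(shape)
    p = cfg.amplitude_weight_power
    for f, kmap, ampmap in entries:
        amp = np.where(ampmap.mask, ampmap.values, 0.0)
        ref = np.nanpercentile(np.where(ampmap.mask, ampmap.values, np.nan), 95)
        floor = cfg.min_amplitude_fraction * (ref if np.isfinite(ref) else 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = 2.0 * np.pi * f / kmap.values
        valid = kmap.mask & (kmap.values > 0) & np.isfinite(c) & (amp > floor)
        c = np.clip(c, None, cfg.sws_cap)
        w = np.where(valid, amp ** p, 0.0)
        num += np.where(valid, w * c, 0.0)
        den += w
    with np.errstate(divide="ignore", invalid="ignore"):
        sws = num / den
    valid = den > 0
    spacing = entries[0][1].spacing
    return ParamMap(np.where(valid, sws, np.nan), "m/s", spacing,
                    mask=valid, name="SWS")


# --------------------------------------------------------------------------
# MDEV
# --------------------------------------------------------------------------

def mdev_invert(fields: Sequence[ComplexWaveField],
                cfg: InversionConfig = MOUSE_INVERSION,
                laplacians: Optional[Sequence[np.ndarray]] = None,
                ) -> Tuple[ParamMap, ParamMap]:
    """Multifrequency dual elasto-visco inversion: (|G*| Pa, loss angle rad).

    ``fields`` are the smoothed/low-passed (NOT directionally decomposed)
    wave fields, one per (frequency, component).  Laplacians are computed
    with the central-2nd scheme unless supplied.  With
    ``cfg.dispersion_correction`` each Laplacian is rescaled voxel-wise by
    the discrete dispersion factor evaluated at the field's own
    phase-gradient wavenumber components, removing the known |G*| bias.
    """
    if len(fields) == 0:
        raise ValueError("no wave fields given")
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise ValueError("fields must share one grid")
    if laplacians is None:
        laplacians = [laplacian(f.values, f.spacing) for f in fields]
    elif len(laplacians) != len(fields):
        raise ValueError("need one Laplacian per field")

    shape = fields[0].shape
    num_g = np.zeros(shape)
    den_g = np.zeros(shape)
    num_phi = np.zeros(shape)
    den_phi = np.zeros(shape)
    amp_total = np.zeros(shape)
    for f, lap in zip(fields, laplacians):
        lap = np.asarray(lap, dtype=complex)
        if cfg.dispersion_correction:
            lap = lap * _dispersion_factor_map(f)
        absu = np.abs(f.values)
        abslap = np.abs(lap)
        num_g += f.omega ** 2 * absu
        den_g += abslap
        num_phi += np.real(np.conj(f.values) * lap)
        den_phi += absu * abslap
        amp_total += absu

    mask = np.logical_and.reduce([f.mask for f in fields])
    ref = np.nanpercentile(np.where(mask, amp_total, np.nan), 95)
    floor = cfg.min_amplitude_fraction * (ref if np.isfinite(ref) else 0.0)
    valid = mask & (amp_total > floor) & (den_g > 0) & (den_phi > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        gstar = cfg.density * num_g / den_g
        phi = np.arccos(np.clip(-num_phi / den_phi, -1.0, 1.0))
    spacing = fields[0].spacing
    gmap = ParamMap(np.where(valid, gstar, np.nan), "Pa", spacing,
                    mask=valid, name="|G*|")
    pmap = ParamMap(np.where(valid, phi, np.nan), "rad", spacing,
                    mask=valid, name="loss angle")
    return gmap, pmap


def _dispersion_factor_map(field: ComplexWaveField) -> np.ndarray:
    """Voxel-wise discrete-Laplacian correction factor from the field's own
    phase-gradient wavenumber components (plane-wave transfer function)."""
    h = field.spacing_m
    grads = _masked_gradient(field.values, field.mask, h)
    absu2 = np.abs(field.values) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kvec = [np.arcsin(np.clip(np.imag(np.conj(field.values) * g) / absu2 * hi,
                                  -1.0, 1.0)) / hi
                for g, hi in zip(grads, h)]
    k2 = sum(np.square(k) for k in kvec)
    disc = sum((2.0 / hi * np.sin(k * hi / 2.0)) ** 2
               for k, hi in zip(kvec, h))
    factor = np.ones_like(k2)
    ok = np.isfinite(k2) & np.isfinite(disc) & (disc > 0) & (k2 > 0)
    factor[ok] = k2[ok] / disc[ok]
    return factor
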