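"""Digital viscoelastic phantoms and harmonic shear-wave simulation.

A phantom is a labelled voxel grid in which every region carries a complex
shear modulus G* = |G*|·exp(i·phi).  The wave simulator produces the
steady-state complex displacement of a monofrequency shear wave travelling
through the phantom as a superposition of straight rays: along each
propagation direction the complex wavenumber field is line-integrated, so
the local phase slope and amplitude decay reflect the local material, but
refraction, reflection and mode conversion are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .params import ComplexWaveField, _as_spacing

DENSITY_SOFT_TISSUE = 1000.0  # kg/m^3, standard soft-tissue assumption


# --------------------------------------------------------------------------
# materials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialProps:
    """Viscoelastic material: magnitude and phase of the complex shear modulus.

    Parameters
    ----------
    shear_modulus_magnitude : float
        |G*| in Pa, strictly positive.
    loss_angle : float
        Phase of G* in rad, in [0, pi/2).  0 is purely elastic, the
        pi/2 limit purely viscous.
    density : float
        Mass density in kg/m^3 (default 1000).
    """

    shear_modulus_magnitude: float
    loss_angle: float = 0.0
    density: float = DENSITY_SOFT_TISSUE

    def __post_init__(self):
        if not self.shear_modulus_magnitude > 0:
            raise ValueError("shear_modulus_magnitude must be > 0")
        if not (0.0 <= self.loss_angle < np.pi / 2):
            raise ValueError("loss_angle must lie in [0, pi/2)")
        if not self.density > 0:
            raise ValueError("density must be > 0")

    @property
    def complex_modulus(self) -> complex:
        return self.shear_modulus_magnitude * np.exp(1j * self.loss_angle)

    @property
    def sws(self) -> float:
        """Shear wave speed 2*pi*f / Re(k*), frequency-independent here."""
        return (
            np.sqrt(self.shear_modulus_magnitude / self.density)
            / np.cos(self.loss_angle / 2.0)
        )

    @classmethod
    def from_sws(cls, sws: float, loss_angle: float = 0.0,
                 density: float = DENSITY_SOFT_TISSUE) -> "MaterialProps":
        """Build a material whose shear wave speed equals ``sws`` (m/s)."""
        g = density * (sws * np.cos(loss_angle / 2.0)) ** 2
        return cls(g, loss_angle, density)


def material_wavenumber(m: MaterialProps, f: float) -> complex:
    """Complex shear wavenumber k* in rad/m at frequency ``f`` (Hz).

    k* = 2*pi*f*sqrt(rho/G*) on the branch with Re(k*) > 0 and
    Im(k*) <= 0 (decaying-wave convention).  The ground-truth shear wave
    speed is 2*pi*f / Re(k*).
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if m.loss_angle >= np.pi / 2:
        raise ValueError("loss_angle must be < pi/2")
    omega = 2.0 * np.pi * f
    return omega * np.sqrt(m.density / m.complex_modulus + 0j)


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

class Geometry:
    """Base class for region shapes; coordinates are voxel-centre mm."""

    def contains(self, coords: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class FullGrid(Geometry):
    def contains(self, coords):
        return np.ones(coords.shape[1:], dtype=bool)


@dataclass(frozen=True)
class Ellipsoid(Geometry):
    """Axis-aligned ellipse (2D) or ellipsoid (3D): center and semi-axes in mm."""

    center: Tuple[float, ...]
    semi_axes: Tuple[float, ...]

    def contains(self, coords):
        c = np.asarray(self.center).reshape(-1, *([1] * (coords.ndim - 1)))
        a = np.asarray(self.semi_axes).reshape(-1, *([1] * (coords.ndim - 1)))
        return np.sum(((coords - c) / a) ** 2, axis=0) <= 1.0


@dataclass(frozen=True)
class Sphere(Geometry):
    center: Tuple[float, ...]
    radius: float

    def contains(self, coords):
        c = np.asarray(self.center).reshape(-1, *([1] * (coords.ndim - 1)))
        return np.sum((coords - c) ** 2, axis=0) <= self.radius ** 2


@dataclass(frozen=True)
class Annulus(Geometry):
    """Shell between two concentric ellipses/ellipsoids."""

    center: Tuple[float, ...]
    inner_semi_axes: Tuple[float, ...]
    outer_semi_axes: Tuple[float, ...]

    def contains(self, coords):
        outer = Ellipsoid(self.center, self.outer_semi_axes).contains(coords)
        inner = Ellipsoid(self.center, self.inner_semi_axes).contains(coords)
        return outer & ~inner


@dataclass(frozen=True)
class Box(Geometry):
    lo: Tuple[float, ...]
    hi: Tuple[float, ...]

    def contains(self, coords):
        lo = np.asarray(self.lo).reshape(-1, *([1] * (coords.ndim - 1)))
        hi = np.asarray(self.hi).reshape(-1, *([1] * (coords.ndim - 1)))
        return np.all((coords >= lo) & (coords <= hi), axis=0)


# --------------------------------------------------------------------------
# phantom specification and rasterisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomRegion:
    label: int
    geometry: Geometry
    material: MaterialProps


@dataclass
class PhantomSpec:
    """Labelled grid plus per-region materials.  Label 0 is background."""

    grid_shape: Tuple[int, ...]
    voxel_spacing: Tuple[float, ...]  # mm
    regions: Sequence[PhantomRegion]
    name: str = "phantom"
    background_material: Optional[MaterialProps] = None

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing = _as_spacing(self.voxel_spacing, len(self.grid_shape))
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region label_ids must be unique")
        if 0 in labels:
            raise ValueError("label 0 is reserved for background")

    def voxel_coords(self) -> np.ndarray:
        """(ndim, *grid) array of voxel-centre coordinates in mm."""
        axes = [np.arange(n) * s for n, s in zip(self.grid_shape, self.voxel_spacing)]
        return np.stack(np.meshgrid(*axes, indexing="ij"))


@dataclass
class Phantom:
    """Rasterised phantom: label volume plus per-voxel material maps."""

    spec: PhantomSpec
    labels: np.ndarray
    modulus: np.ndarray      # |G*| in Pa, NaN outside all regions
    loss_angle: np.ndarray   # rad, NaN outside
    density: np.ndarray      # kg/m^3, NaN outside

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def spacing(self):
        return self.spec.voxel_spacing

    def wavenumber_field(self, f: float) -> np.ndarray:
        """Per-voxel complex k* at frequency ``f``; 0 outside the phantom
        unless a background material is set."""
        omega = 2.0 * np.pi * f
        k = np.zeros(self.labels.shape, dtype=complex)
        inside = self.mask
        g = self.modulus[inside] * np.exp(1j * self.loss_angle[inside])
        k[inside] = omega * np.sqrt(self.density[inside] / g)
        if self.spec.background_material is not None:
            k[~inside] = material_wavenumber(self.spec.background_material, f)
        return k


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise a PhantomSpec onto its voxel grid.

    Overlapping regions are an error unless they carry identical materials;
    the error names the first conflicting voxel.
    """
    coords = spec.voxel_coords()
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    modulus = np.full(spec.grid_shape, np.nan)
    loss = np.full(spec.grid_shape, np.nan)
    dens = np.full(spec.grid_shape, np.nan)
    for region in spec.regions:
        inside = region.geometry.contains(coords)
        clash = inside & (labels > 0)
        if np.any(clash):
            prev = labels[clash][0]
            prev_mat = next(r.material for r in spec.regions if r.label == prev)
            if prev_mat != region.material:
                vox = tuple(int(i[0]) for i in np.nonzero(clash))
                raise ValueError(
                    f"regions {prev} and {region.label} overlap with conflicting "
                    f"materials at voxel {vox}"
                )
        labels[inside] = region.label
        modulus[inside] = region.material.shear_modulus_magnitude
        loss[inside] = region.material.loss_angle
        dens[inside] = region.material.density
    return Phantom(spec, labels, modulus, loss, dens)


# --------------------------------------------------------------------------
# wave simulation
# --------------------------------------------------------------------------

@dataclass
class WaveSimConfig:
    """Source configuration for the straight-ray harmonic wave simulator."""

    frequencies: Sequence[float]
    directions: Sequence[Sequence[float]]
    amplitudes: Optional[Sequence[float]] = None
    phase_offsets: Optional[Sequence[float]] = None
    snr: Optional[float] = None   # linear amplitude SNR; None = noiseless
    seed: Optional[int] = None

    def __post_init__(self):
        self.frequencies = tuple(float(f) for f in self.frequencies)
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")
        dirs = [np.asarray(d, dtype=float) for d in self.directions]
        if len(dirs) == 0:
            raise ValueError("at least one propagation direction is required")
        for d in dirs:
            n = np.linalg.norm(d)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError("directions must be unit vectors")
        self.directions = dirs
        if self.amplitudes is None:
            self.amplitudes = (1.0,) * len(dirs)
        self.amplitudes = tuple(float(a) for a in self.amplitudes)
        if len(self.amplitudes) != len(dirs):
            raise ValueError("need one amplitude per direction")
        if self.phase_offsets is None:
            self.phase_offsets = (0.0,) * len(dirs)
        self.phase_offsets = tuple(float(p) for p in self.phase_offsets)
        if len(self.phase_offsets) != len(dirs):
            raise ValueError("need one phase offset per direction")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")


def accumulated_wavenumber(kstar: np.ndarray, spacing_mm, direction,
                           step_mm: Optional[float] = None) -> np.ndarray:
    """Line-integrate a complex wavenumber field along a propagation direction.

    Returns the complex accumulated phase K(x) = integral of k* along the ray
    reaching voxel x from the entry plane, in rad.  Midpoint rule with
    nearest-neighbour material lookup; samples beyond the grid clamp to the
    nearest edge voxel so a homogeneous phantom yields an exact plane wave.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    spacing = np.asarray(_as_spacing(spacing_mm, kstar.ndim))
    if step_mm is None:
        step_mm = 0.5 * spacing.min()
    axes = [np.arange(n) * s for n, s in zip(kstar.shape, spacing)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))  # mm
    t = np.tensordot(d, coords, axes=1)                   # ray parameter, mm
    t0 = t.min()
    n_steps = int(np.ceil((t.max() - t0) / step_mm))
    K = np.zeros(kstar.shape, dtype=complex)
    re, im = kstar.real, kstar.imag
    for j in range(n_steps):
        s = t0 + (j + 0.5) * step_mm
        # length of this step actually traversed by each voxel's ray
        w = np.clip(t - (t0 + j * step_mm), 0.0, step_mm) * 1e-3  # m
        if not np.any(w > 0):
            continue
        # sample point x - (t(x) - s) d, in index units
        pts = [
            (coords[a] - (t - s) * d[a]) / spacing[a]
            for a in range(kstar.ndim)
        ]
        pts = np.stack([p.ravel() for p in pts])
        kr = map_coordinates(re, pts, order=0, mode="nearest").reshape(kstar.shape)
        ki = map_coordinates(im, pts, order=0, mode="nearest").reshape(kstar.shape)
        K += w * (kr + 1j * ki)
    return K


def simulate_plane_wavefield(phantom: Phantom, f: float, cfg: WaveSimConfig,
                             component: str = "z") -> ComplexWaveField:
    """Simulate the complex displacement field at one frequency.

    u(x) = sum_d A_d exp(i phi0_d) exp(i Re K_d(x)) exp(Im K_d(x)) with
    K_d the accumulated complex wavenumber along direction d (Im K <= 0,
    so lossy materials attenuate the wave along propagation).  Optional
    additive complex Gaussian noise at the configured amplitude SNR.
    """
    kfield = phantom.wavenumber_field(f)
    u = np.zeros(phantom.labels.shape, dtype=complex)
    for d, amp, ph0 in zip(cfg.directions, cfg.amplitudes, cfg.phase_offsets):
        K = accumulated_wavenumber(kfield, phantom.spacing, d)
        u += amp * np.exp(1j * ph0) * np.exp(1j * K.real + K.imag)
    mask = phantom.mask
    if cfg.snr is not None:
        rng = np.random.default_rng(cfg.seed)
        sd = np.mean(np.abs(u[mask])) / cfg.snr if mask.any() else np.mean(np.abs(u)) / cfg.snr
        noise = (rng.standard_normal(u.shape) + 1j * rng.standard_normal(u.shape))
        u = u + sd / np.sqrt(2.0) * noise
    return ComplexWaveField(u, f, phantom.spacing, mask=mask, component=component)


def simulate_multifrequency(phantom: Phantom, cfg: WaveSimConfig,
                            component: str = "z"):
    """One ComplexWaveField per configured frequency (independent noise)."""
    fields = []
    for i, f in enumerate(cfg.frequencies):
        sub = WaveSimConfig(
            frequencies=(f,), directions=cfg.directions, amplitudes=cfg.amplitudes,
            phase_offsets=cfg.phase_offsets, snr=cfg.snr,
            seed=None if cfg.seed is None else cfg.seed + 1000 * i,
        )
        fields.append(simulate_plane_wavefield(phantom, f, sub, component=component))
    return fields


# --------------------------------------------------------------------------
# convenience phantom builders
# --------------------------------------------------------------------------

MOUSE_GRID = (90, 60)
MOUSE_SPACING = (0.18, 0.18)  # mm
MOUSE_FREQUENCIES = (1000.0, 1100.0, 1200.0, 1300.0, 1400.0)
HUMAN_FREQUENCIES = (20.0, 25.0, 30.0, 35.0)


def homogeneous_phantom(material: MaterialProps,
                        grid_shape=MOUSE_GRID,
                        voxel_spacing=MOUSE_SPACING,
                        name: str = "homogeneous") -> Phantom:
    spec = PhantomSpec(grid_shape, voxel_spacing,
                       [PhantomRegion(1, FullGrid(), material)], name=name)
    return build_phantom(spec)


def cortex_shell_phantom(cortex: MaterialProps, deep: MaterialProps,
                         grid_shape=MOUSE_GRID, voxel_spacing=MOUSE_SPACING,
                         name: str = "cortex-shell") -> Phantom:
    """Two-compartment brain-like phantom: elliptical cortical shell (label 1)
    around a deep-tissue core (label 2), embedded in a background that
    propagates with the deep material so waves reach the core undistorted."""
    shape = np.asarray(grid_shape, float)
    sp = np.asarray(_as_spacing(voxel_spacing, len(grid_shape)))
    center = tuple((shape - 1) * sp / 2.0)
    outer = tuple(0.46 * shape * sp)
    inner = tuple(0.30 * shape * sp)
    spec = PhantomSpec(
        grid_shape, voxel_spacing,
        [
            PhantomRegion(1, Annulus(center, inner, outer), cortex),
            PhantomRegion(2, Ellipsoid(center, inner), deep),
        ],
        name=name,
        background_material=deep,
    )
    return build_phantom(spec)
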