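"""Shared voxel-map containers.

Axis convention throughout the package: arrays are indexed in (slice, row,
column) order for 3D and (row, column) for 2D; ``spacing`` stores the voxel
size per axis in millimetres, in the same order.  All wavenumber arithmetic
converts spacing to metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

#: physical units a ParamMap may carry
VALID_UNITS = ("m/s", "rad", "Pa", "ms", "mm^2/s", "a.u.", "1", "%", "1/m", "rad/m")


def _as_spacing(spacing, ndim: int) -> Tuple[float, ...]:
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) == 1:
        spacing = spacing * ndim
    if len(spacing) != ndim:
        raise ValueError(f"spacing has {len(spacing)} entries for a {ndim}-D grid")
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be positive")
    return spacing


@dataclass
class ParamMap:
    """Scalar voxel map with a physical unit and validity mask.

    Masked voxels carry NaN in ``values`` — never silent zeros.
    """

    values: np.ndarray
    unit: str
    spacing: Tuple[float, ...]  # mm per axis
    mask: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        self.spacing = _as_spacing(self.spacing, self.values.ndim)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values shape")
            self.mask = self.mask & np.isfinite(self.values)
        # enforce the sentinel: values outside the mask are NaN
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def shape(self):
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        """Return the valid voxel values as a 1-D array."""
        return self.values[self.mask]

    def eroded(self, n: int = 1) -> "ParamMap":
        """Shrink the validity mask by ``n`` voxels (binary erosion)."""
        from scipy.ndimage import binary_erosion

        m = binary_erosion(self.mask, iterations=n) if n > 0 else self.mask
        return replace(self, mask=m, values=np.where(m, self.values, np.nan))


@dataclass
class ComplexWaveField:
    """Complex harmonic displacement field at one vibration frequency.

    ``values`` holds the complex displacement amplitude per voxel in
    arbitrary units; ``component`` labels the encoded motion axis
    ("z" for the single thru-plane component of the 2D mouse protocol).
    """

    values: np.ndarray
    frequency: float  # Hz
    spacing: Tuple[float, ...]  # mm per axis
    mask: Optional[np.ndarray] = None
    component: str = "z"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        self.spacing = _as_spacing(self.spacing, self.values.ndim)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values shape")

    @property
    def shape(self):
        return self.values.shape

    @property
    def spacing_m(self) -> Tuple[float, ...]:
        return tuple(s * 1e-3 for s in self.spacing)

    def with_values(self, values: np.ndarray) -> "ComplexWaveField":
        return replace(self, values=np.asarray(values, dtype=complex))

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency
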