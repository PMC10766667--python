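"""Mask construction, regional averaging, and group effect maps.

The synthetic atlas mimics the parcellation used for the mouse analyses: an
elliptical cortical shell, deep gray-matter nuclei (hippocampus,
caudoputamen, pallidum, thalamus, hypothalamus, midbrain, striatum) as
blobs inside it, and ventricle slots that are excluded from every tissue
mask because wave propagation in fluid cannot be analysed.  "Whole brain"
and "deep gray matter" are derived masks, not stored labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ParamMap, _as_spacing
from .phantom import Annulus, Ellipsoid, Geometry

MOUSE_REGION_NAMES = (
    "cortex", "hippocampus", "caudoputamen", "pallidum", "thalamus",
    "hypothalamus", "midbrain", "striatum",
)


@dataclass
class AtlasLabels:
    """Integer label volume plus the region-name table."""

    labels: np.ndarray
    names: Dict[int, str]
    spacing: tuple
    ventricle_label: Optional[int] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.spacing = _as_spacing(self.spacing, self.labels.ndim)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in volume but "
                             "absent from the name table")

    def id_of(self, name: str) -> int:
        for lid, n in self.names.items():
            if n == name:
                return lid
        raise KeyError(f"unknown region {name!r}")

    def mask_of(self, name: str) -> np.ndarray:
        """Region mask by name; 'whole brain' and 'deep gray matter' are
        derived (ventricles always excluded)."""
        vent = (self.labels == self.ventricle_label
                if self.ventricle_label is not None
                else np.zeros(self.labels.shape, bool))
        if name == "whole brain":
            return (self.labels > 0) & ~vent
        if name == "deep gray matter":
            return ((self.labels > 0) & ~vent
                    & (self.labels != self.id_of("cortex")))
        return (self.labels == self.id_of(name)) & ~vent


def mouse_atlas(grid_shape=(90, 60), voxel_spacing=(0.18, 0.18)) -> AtlasLabels:
    """Synthetic 2D mouse-brain parcellation on the MRE grid."""
    shape = np.asarray(grid_shape, float)
    sp = np.asarray(_as_spacing(voxel_spacing, len(grid_shape)))
    extent = (shape - 1) * sp
    c = extent / 2.0
    axes = [np.arange(n) * s for n, s in zip(grid_shape, sp)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))

    outer = 0.46 * shape * sp
    inner = 0.30 * shape * sp
    geoms: Dict[int, Geometry] = {
        1: Annulus(tuple(c), tuple(inner), tuple(outer)),               # cortex
        2: Ellipsoid((c[0] - 0.16 * extent[0], c[1]),
                     (0.08 * extent[0], 0.12 * extent[1])),             # hippocampus
        3: Ellipsoid((c[0], c[1] - 0.14 * extent[1]),
                     (0.09 * extent[0], 0.08 * extent[1])),             # caudoputamen
        4: Ellipsoid((c[0], c[1] + 0.14 * extent[1]),
                     (0.05 * extent[0], 0.06 * extent[1])),             # pallidum
        5: Ellipsoid((c[0] + 0.10 * extent[0], c[1]),
                     (0.06 * extent[0], 0.08 * extent[1])),             # thalamus
        6: Ellipsoid((c[0] + 0.20 * extent[0], c[1]),
                     (0.04 * extent[0], 0.06 * extent[1])),             # hypothalamus
        7: Ellipsoid((c[0] + 0.16 * extent[0], c[1] - 0.16 * extent[1]),
                     (0.04 * extent[0], 0.05 * extent[1])),             # midbrain
        8: Ellipsoid((c[0] - 0.16 * extent[0], c[1] + 0.16 * extent[1]),
                     (0.05 * extent[0], 0.05 * extent[1])),             # striatum
    }
    labels = np.zeros(tuple(int(n) for n in grid_shape), dtype=np.int32)
    # inner parenchyma (unlabelled deep tissue) stays 0 but inside the brain:
    # paint brain interior with a generic deep label so whole-brain covers it
    interior = Ellipsoid(tuple(c), tuple(inner)).contains(coords)
    labels[interior] = 9
    for lid, g in geoms.items():
        labels[g.contains(coords)] = lid
    # two small ventricle slots near the centre
    vent = (Ellipsoid((c[0] - 0.04 * extent[0], c[1] - 0.05 * extent[1]),
                      (0.025 * extent[0], 0.03 * extent[1])).contains(coords)
            | Ellipsoid((c[0] - 0.04 * extent[0], c[1] + 0.05 * extent[1]),
                        (0.025 * extent[0], 0.03 * extent[1])).contains(coords))
    labels[vent] = 10
    names = dict(enumerate(MOUSE_REGION_NAMES, start=1))
    names[9] = "deep parenchyma"
    names[10] = "ventricles"
    return AtlasLabels(labels, names, tuple(sp), ventricle_label=10)


# --------------------------------------------------------------------------
# mask algebra
# --------------------------------------------------------------------------

def threshold_probability_mask(prob_map: np.ndarray, threshold: float) -> np.ndarray:
    """Strict-inequality probability threshold: mask = prob > threshold."""
    prob = np.asarray(prob_map, dtype=float)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if np.nanmin(prob) < 0 or np.nanmax(prob) > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return prob > threshold


def subtract_mask(base: np.ndarray, exclusion: np.ndarray) -> np.ndarray:
    """Set difference base \\ exclusion; warns when nothing survives."""
    base = np.asarray(base, bool)
    exclusion = np.asarray(exclusion, bool)
    if base.shape != exclusion.shape:
        raise ValueError("mask grids do not match")
    out = base & ~exclusion
    if base.any() and not out.any():
        warnings.warn("exclusion mask covers the entire base mask", stacklevel=2)
    return out


# --------------------------------------------------------------------------
# regional statistics
# --------------------------------------------------------------------------

def region_means(pmap: ParamMap, atlas: AtlasLabels,
                 regions: Optional[Sequence[str]] = None,
                 mask: Optional[np.ndarray] = None,
                 metric: str = "value") -> pd.DataFrame:
    """Mean parameter value per region: rows (region, metric, value, n_voxels).

    The mean runs over region-mask AND the optional extra mask AND the
    map's own validity mask; empty intersections yield no row and a warning.
    """
    if pmap.shape != atlas.labels.shape:
        raise ValueError("map and atlas are on different grids")
    if regions is None:
        regions = list(MOUSE_REGION_NAMES) + ["deep gray matter", "whole brain"]
    rows = []
    for name in regions:
        try:
            rmask = atlas.mask_of(name)
        except KeyError:
            raise ValueError(f"unknown region {name!r}")
        sel = rmask & pmap.mask
        if mask is not None:
            sel &= mask
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"region {name!r} has no valid voxels", stacklevel=2)
            continue
        rows.append({"region": name, "metric": metric,
                     "value": float(pmap.values[sel].mean()), "n_voxels": n})
    return pd.DataFrame(rows, columns=["region", "metric", "value", "n_voxels"])


def group_mean_map(maps: Sequence[ParamMap],
                   min_fraction: float = 0.5) -> ParamMap:
    """Voxelwise mean over subjects, valid where >= ``min_fraction`` of
    subjects are unmasked."""
    if len(maps) == 0:
        raise ValueError("no maps given")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("maps must share one grid")
    stack = np.stack([m.values for m in maps])
    counts = np.isfinite(stack).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    valid = counts >= min_fraction * len(maps)
    return ParamMap(np.where(valid, mean, np.nan), maps[0].unit,
                    maps[0].spacing, mask=valid, name="group mean")


def percent_change_map(peak: ParamMap, baseline: ParamMap) -> ParamMap:
    """Effect map 100 * (peak - baseline) / baseline (%); voxels with
    non-positive baseline are masked."""
    if peak.shape != baseline.shape:
        raise ValueError("maps are on different grids")
    valid = peak.mask & baseline.mask & (baseline.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (peak.values - baseline.values) / baseline.values
    return ParamMap(np.where(valid, change, np.nan), "%", peak.spacing,
                    mask=valid, name="percent change")


def delta_metric(baseline: pd.Series, peak: pd.Series) -> pd.Series:
    """Per-subject change peak - baseline for paired subjects (indexes must
    match one-to-one)."""
    if set(baseline.index) != set(peak.index):
        raise ValueError("unpaired subjects between baseline and peak")
    peak = peak.reindex(baseline.index)
    return peak - baseline
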