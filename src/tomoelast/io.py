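"""NIfTI / sidecar / table input and output.

Wave fields are stored as paired real/imaginary NIfTI volumes with a JSON
sidecar carrying frequency, component and grid spacing; parameter maps are
single NIfTI volumes whose unit travels in the header description and in a
JSON provenance sidecar.  Region tables are TSV; cohort and phantom
configurations are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .params import ComplexWaveField, ParamMap
from .regions import AtlasLabels


def _affine(spacing_mm, ndim: int) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing_mm[:3]):
        aff[i, i] = s
    return aff


def _to_3d(values: np.ndarray) -> np.ndarray:
    return values if values.ndim == 3 else values[..., None]


def _from_nifti(img) -> np.ndarray:
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return data


def save_wavefield(field: ComplexWaveField, stem: Path) -> None:
    """Write <stem>_real.nii.gz, <stem>_imag.nii.gz and <stem>.json."""
    stem = Path(stem)
    aff = _affine(field.spacing, field.values.ndim)
    nib.save(nib.Nifti1Image(_to_3d(field.values.real), aff),
             str(stem) + "_real.nii.gz")
    nib.save(nib.Nifti1Image(_to_3d(field.values.imag), aff),
             str(stem) + "_imag.nii.gz")
    nib.save(nib.Nifti1Image(_to_3d(field.mask.astype(np.uint8)), aff),
             str(stem) + "_mask.nii.gz")
    sidecar = {"frequency_hz": field.frequency, "component": field.component,
               "spacing_mm": list(field.spacing)}
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_wavefield(stem: Path) -> ComplexWaveField:
    stem = Path(stem)
    meta = json.loads(Path(str(stem) + ".json").read_text())
    real = _from_nifti(nib.load(str(stem) + "_real.nii.gz"))
    imag = _from_nifti(nib.load(str(stem) + "_imag.nii.gz"))
    mask_path = Path(str(stem) + "_mask.nii.gz")
    mask = (_from_nifti(nib.load(str(mask_path))) > 0
            if mask_path.exists() else None)
    return ComplexWaveField(real + 1j * imag, meta["frequency_hz"],
                            tuple(meta["spacing_mm"]), mask=mask,
                            component=meta.get("component", "z"))


def save_parammap(pmap: ParamMap, path: Path,
                  provenance: Optional[dict] = None) -> None:
    path = Path(path)
    aff = _affine(pmap.spacing, pmap.values.ndim)
    img = nib.Nifti1Image(_to_3d(pmap.values), aff)
    img.header["descrip"] = f"unit={pmap.unit}".encode()[:80]
    nib.save(img, str(path))
    sidecar = {"unit": pmap.unit, "spacing_mm": list(pmap.spacing),
               "name": pmap.name}
    if provenance:
        sidecar["provenance"] = provenance
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def load_parammap(path: Path) -> ParamMap:
    path = Path(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    values = _from_nifti(nib.load(str(path)))
    return ParamMap(values, meta["unit"], tuple(meta["spacing_mm"]),
                    name=meta.get("name", ""))


def save_atlas(atlas: AtlasLabels, path: Path) -> None:
    path = Path(path)
    aff = _affine(atlas.spacing, atlas.labels.ndim)
    nib.save(nib.Nifti1Image(_to_3d(atlas.labels.astype(np.int16)), aff),
             str(path))
    sidecar = {"names": {str(k): v for k, v in atlas.names.items()},
               "spacing_mm": list(atlas.spacing),
               "ventricle_label": atlas.ventricle_label}
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def load_atlas(path: Path) -> AtlasLabels:
    path = Path(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    labels = _from_nifti(nib.load(str(path))).astype(np.int32)
    return AtlasLabels(labels, {int(k): v for k, v in meta["names"].items()},
                       tuple(meta["spacing_mm"]),
                       ventricle_label=meta.get("ventricle_label"))


def save_region_table(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_region_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_cohort_config(path: Path) -> dict:
    """Read a cohort YAML into keyword arguments for CohortSpec."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("cohort config must be a YAML mapping")
    return cfg
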