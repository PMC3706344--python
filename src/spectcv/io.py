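"""File I/O: NIfTI volumes, projection stacks, CSV/JSON reports, YAML plans."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cvmap import CVMatrix, FrequencyFunction
from .volumes import ActivityVolume, AttenuationMap, LungMask, ProjectionSet


def _affine(pitch_mm: float) -> np.ndarray:
    return np.diag([pitch_mm, pitch_mm, pitch_mm, 1.0])


def save_volume(path, vol: ActivityVolume | AttenuationMap):
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.voxel_pitch_mm))
    nib.save(img, str(path))


def load_volume(path, provenance: str = "reconstruction") -> ActivityVolume:
    img = nib.load(str(path))
    pitch = float(img.header.get_zooms()[0])
    return ActivityVolume(np.asarray(img.dataobj, dtype=np.float64), pitch, provenance)


def load_attenuation(path) -> AttenuationMap:
    img = nib.load(str(path))
    pitch = float(img.header.get_zooms()[0])
    return AttenuationMap(np.asarray(img.dataobj, dtype=np.float64), pitch)


def save_mask(path, mask: LungMask):
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_pitch_mm))
    nib.save(img, str(path))


def load_mask(path, variant: str = "full") -> LungMask:
    img = nib.load(str(path))
    pitch = float(img.header.get_zooms()[0])
    return LungMask(np.asarray(img.dataobj) > 0, pitch, variant=variant)


def save_cv_matrix(path, cvm: CVMatrix):
    """CV matrix as NIfTI with NaN at invalid centres."""
    img = nib.Nifti1Image(cvm.values.astype(np.float32), _affine(cvm.voxel_pitch_mm))
    nib.save(img, str(path))


def save_projections(path, proj: ProjectionSet):
    """Projection stack as NIfTI (angle as leading axis) + JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(proj.images.astype(np.float32), np.eye(4))
    nib.save(img, str(path))
    sidecar = {
        "angles_deg": proj.angles_deg.tolist(),
        "pixel_pitch_mm": proj.pixel_pitch_mm,
        "kind": proj.kind,
        "total_counts": proj.total_counts(),
        **{k: v for k, v in proj.meta.items() if _jsonable(v)},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_projections(path) -> ProjectionSet:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ProjectionSet(
        np.asarray(sidecar["angles_deg"]),
        np.asarray(img.dataobj, dtype=np.float64),
        float(sidecar["pixel_pitch_mm"]),
        kind=sidecar.get("kind", "mean"),
        meta={k: v for k, v in sidecar.items()
              if k not in ("angles_deg", "pixel_pitch_mm", "kind")},
    )


def save_centres(path, centres: np.ndarray, pitch_mm: float):
    """Lesion centres as CSV in 0-based voxel and mm coordinates."""
    centres = np.asarray(centres, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(
        {
            "z_voxel": centres[:, 0], "y_voxel": centres[:, 1], "x_voxel": centres[:, 2],
            "z_mm": centres[:, 0] * pitch_mm, "y_mm": centres[:, 1] * pitch_mm,
            "x_mm": centres[:, 2] * pitch_mm,
        }
    )
    with open(path, "w") as fh:
        fh.write("# lesion centres, 0-based voxel indices (z,y,x) and mm\n")
        df.to_csv(fh, index=False)


def save_frequency_function(path, ff: FrequencyFunction):
    pd.DataFrame(
        {"bin_left_percent": ff.bin_left, "frequency_percent": ff.frequencies_percent}
    ).to_csv(path, index=False)


def load_frequency_function(path) -> FrequencyFunction:
    df = pd.read_csv(path)
    left = df["bin_left_percent"].to_numpy(float)
    width = float(left[1] - left[0]) if len(left) > 1 else 1.0
    return FrequencyFunction(left, df["frequency_percent"].to_numpy(float), width)


def save_json(path, payload: dict):
    Path(path).write_text(json.dumps(payload, indent=2, default=_coerce))


def load_plan_yaml(path) -> dict:
    """Raw plan dictionary from a YAML config (see cli for the schema)."""
    return yaml.safe_load(Path(path).read_text())


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
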