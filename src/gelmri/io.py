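"""File I/O: NIfTI-1 images with JSON sidecars, masks, and CSV tables.

Image data travel as NIfTI-1 (via nibabel) with acquisition metadata
(inversion times, image TR, flip angle) in a JSON sidecar next to the
image, mirroring the common sidecar convention for quantitative MRI.
Tabular data (calibration ladders, volume and release series, rheology
sweeps) are plain CSV handled through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantoms import RheologyTrace
from .t1fit import InversionRecoverySeries, RelaxationMap

__all__ = [
    "save_series",
    "load_series",
    "save_map",
    "load_map",
    "save_mask",
    "load_mask",
    "read_calibration_csv",
    "read_rheology_csv",
    "write_rheology_csv",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(voxel_size_mm[:3]):
        aff[i, i] = v
    return aff


def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return image_path.with_name(name[: -len(suffix)] + ".json")
    return image_path.with_suffix(".json")


def save_series(series: InversionRecoverySeries, path) -> Path:
    """Write a 4-D magnitude series as NIfTI-1 plus a JSON sidecar."""
    path = Path(path)
    data = series.data
    if data.ndim != 4:
        raise ValueError("expect spatial 3-D + inversion-time axis")
    img = nib.Nifti1Image(data.astype(np.float32), _affine(series.voxel_size_mm))
    nib.save(img, path)
    meta = {
        "inversion_times_s": series.inversion_times_s.tolist(),
        "tr_img_s": series.tr_img_s,
        "flip_angle_deg": series.flip_angle_deg,
        "voxel_size_mm": list(series.voxel_size_mm),
        "series_id": series.series_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    if series.mask is not None:
        save_mask(series.mask, series.voxel_size_mm,
                  path.parent / (path.name.split(".nii")[0] + "_mask.nii.gz"))
    return path


def load_series(path) -> InversionRecoverySeries:
    """Load a 4-D series written by :func:`save_series`."""
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    mask_path = path.parent / (path.name.split(".nii")[0] + "_mask.nii.gz")
    mask = None
    if mask_path.exists():
        mask = np.asarray(nib.load(mask_path).dataobj) > 0
    return InversionRecoverySeries(
        data=np.asarray(img.dataobj, dtype=float),
        inversion_times_s=np.asarray(meta["inversion_times_s"]),
        tr_img_s=float(meta["tr_img_s"]),
        flip_angle_deg=float(meta["flip_angle_deg"]),
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        mask=mask,
        series_id=meta.get("series_id", ""),
    )


def save_map(rmap: RelaxationMap, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write a T1 map (s) and its acceptance mask; provenance in a sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(rmap.t1_s.astype(np.float32), _affine(voxel_size_mm))
    nib.save(img, path)
    save_mask(rmap.mask, voxel_size_mm,
              path.parent / (path.name.split(".nii")[0] + "_mask.nii.gz"))
    _sidecar_path(path).write_text(json.dumps(rmap.provenance, indent=2, default=str))
    return path


def load_map(path) -> RelaxationMap:
    path = Path(path)
    t1 = np.asarray(nib.load(path).dataobj, dtype=float)
    mask_path = path.parent / (path.name.split(".nii")[0] + "_mask.nii.gz")
    mask = np.asarray(nib.load(mask_path).dataobj) > 0 if mask_path.exists() else t1 > 0
    sidecar = _sidecar_path(path)
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RelaxationMap(t1_s=t1, mask=mask, provenance=prov)


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj) > 0


def read_calibration_csv(path) -> pd.DataFrame:
    """Read a relaxivity calibration table.

    Expects columns ``T1_s`` and at least one of ``concentration_mM`` /
    ``concentration_mg_per_ml`` (the latter converted at 74 kDa unless a
    ``molecular_weight_kda`` column is present); optional ``medium``.
    """
    df = pd.read_csv(path)
    if "T1_s" not in df.columns:
        raise ValueError("calibration CSV needs a T1_s column")
    if "concentration_mM" not in df.columns:
        if "concentration_mg_per_ml" not in df.columns:
            raise ValueError("calibration CSV needs a concentration column")
        mw = df.get("molecular_weight_kda", 74.0)
        df["concentration_mM"] = df["concentration_mg_per_ml"] / mw
    return df


def read_rheology_csv(path) -> RheologyTrace:
    """Read a rheology time sweep (columns time_s, G_prime_Pa[, G_double_prime_Pa])."""
    df = pd.read_csv(path)
    for col in ("time_s", "G_prime_Pa"):
        if col not in df.columns:
            raise ValueError(f"rheology CSV needs a {col} column")
    gpp = df["G_double_prime_Pa"].to_numpy() if "G_double_prime_Pa" in df.columns else None
    return RheologyTrace(
        times_s=df["time_s"].to_numpy(dtype=float),
        g_prime_pa=df["G_prime_Pa"].to_numpy(dtype=float),
        g_double_prime_pa=gpp,
    )


def write_rheology_csv(trace: RheologyTrace, path) -> Path:
    path = Path(path)
    cols = {"time_s": trace.times_s, "G_prime_Pa": trace.g_prime_pa}
    if trace.g_double_prime_pa is not None:
        cols["G_double_prime_Pa"] = trace.g_double_prime_pa
    pd.DataFrame(cols).to_csv(path, index=False)
    return path
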