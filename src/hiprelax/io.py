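"""Readers and writers for the pipeline's on-disk formats.

Conventions, enforced here once: voxel indexing is 0-based and slices-first
(slices, rows, cols); all times are milliseconds; all angles degrees.  Maps, masks,
label grids and p/z-maps are NIfTI volumes (data stored so that the first NIfTI axis
is the slice axis); echo series are 4-D NIfTI with a JSON timing sidecar
``{"contrast": ..., "times_ms": [...]}``; tables are CSV with documented, ordered
columns.  Uncompressed ``.nii`` output is deterministic byte-for-byte; ``.nii.gz`` is
accepted on read and written on request.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasGeometry, SubregionLabels
from .errors import InputError
from .relaxometry import Contrast, EchoSeries, RelaxationMap

__all__ = [
    "write_map",
    "read_map",
    "write_series",
    "read_series",
    "write_table",
    "read_table",
    "write_atlas",
    "read_atlas",
    "write_group_stats",
    "read_group_stats",
    "write_labels",
    "read_labels",
    "write_volume",
    "read_volume",
]

_IDENTITY = np.eye(4)


def write_volume(path, array: np.ndarray, affine: np.ndarray | None = None) -> Path:
    """Write one volume as NIfTI; boolean arrays are stored as uint8 0/1."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, _IDENTITY if affine is None else affine)
    img.header.set_data_dtype(arr.dtype)
    nib.save(img, path)
    return path


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def _sidecar_path(prefix: Path) -> Path:
    return prefix.with_suffix("").with_suffix("") if prefix.suffix else prefix


def write_map(prefix, rmap: RelaxationMap, affine: np.ndarray | None = None) -> dict[str, Path]:
    """Write a relaxation map as ``<prefix>_values.nii``, ``<prefix>_valid.nii``,
    ``<prefix>_amplitudes.nii`` and a ``<prefix>.json`` metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": write_volume(prefix.parent / f"{prefix.name}_values.nii", rmap.values, affine),
        "valid": write_volume(prefix.parent / f"{prefix.name}_valid.nii", rmap.valid, affine),
        "amplitudes": write_volume(prefix.parent / f"{prefix.name}_amplitudes.nii", rmap.amplitudes, affine),
    }
    meta = {
        "contrast": rmap.contrast.value,
        "upper_threshold_ms": None if math.isinf(rmap.upper_threshold_ms) else rmap.upper_threshold_ms,
    }
    meta_path = prefix.parent / f"{prefix.name}.json"
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    paths["meta"] = meta_path
    return paths


def read_map(prefix) -> RelaxationMap:
    prefix = Path(prefix)
    meta_path = prefix.parent / f"{prefix.name}.json"
    if not meta_path.exists():
        raise InputError(f"missing map metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    try:
        contrast = Contrast(meta["contrast"])
    except (KeyError, ValueError) as exc:
        raise InputError(f"unknown or missing contrast tag in {meta_path}") from exc
    values, _ = read_volume(prefix.parent / f"{prefix.name}_values.nii")
    valid, _ = read_volume(prefix.parent / f"{prefix.name}_valid.nii")
    amplitudes, _ = read_volume(prefix.parent / f"{prefix.name}_amplitudes.nii")
    thr = meta.get("upper_threshold_ms")
    return RelaxationMap(
        values=np.asarray(values, dtype=float),
        amplitudes=np.asarray(amplitudes, dtype=float),
        valid=np.asarray(valid, dtype=bool),
        contrast=contrast,
        upper_threshold_ms=math.inf if thr is None else float(thr),
    )


def write_series(prefix, series: EchoSeries, affine: np.ndarray | None = None) -> dict[str, Path]:
    """Write an echo series as a 4-D NIfTI plus a JSON timing sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nii = write_volume(prefix.parent / f"{prefix.name}_series.nii", series.signals, affine)
    sidecar = prefix.parent / f"{prefix.name}.json"
    sidecar.write_text(
        json.dumps(
            {"contrast": series.contrast.value, "times_ms": [float(t) for t in series.times_ms]},
            sort_keys=True,
            indent=1,
        )
        + "\n"
    )
    return {"series": nii, "sidecar": sidecar}


def read_series(prefix) -> EchoSeries:
    prefix = Path(prefix)
    sidecar = prefix.parent / f"{prefix.name}.json"
    if not sidecar.exists():
        raise InputError(f"missing series sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "times_ms" not in meta or "contrast" not in meta:
        raise InputError(f"malformed series sidecar {sidecar}: needs 'contrast' and 'times_ms'")
    signals, _ = read_volume(prefix.parent / f"{prefix.name}_series.nii")
    signals = np.asarray(signals, dtype=float)
    times = np.asarray(meta["times_ms"], dtype=float)
    if signals.ndim != 4 or signals.shape[-1] != times.size:
        raise InputError(
            f"series has {signals.shape[-1] if signals.ndim == 4 else '?'} volumes but "
            f"sidecar lists {times.size} times"
        )
    return EchoSeries(signals=signals, times_ms=times, contrast=Contrast(meta["contrast"]))


def write_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path, expected_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table; unknown extra columns are preserved with a warning."""
    table = pd.read_csv(path)
    if expected_columns is not None:
        missing = [c for c in expected_columns if c not in table.columns]
        if missing:
            raise InputError(f"{path}: missing required columns {missing}")
        extra = [c for c in table.columns if c not in expected_columns]
        if extra:
            warnings.warn(f"{path}: unknown extra columns {extra} preserved", stacklevel=2)
    return table


def write_atlas(directory, geom: AtlasGeometry) -> Path:
    """Persist an atlas as two mask volumes plus ``atlas.yaml`` geometry metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(directory / "femur_mask.nii", geom.femur_mask)
    write_volume(directory / "acetab_mask.nii", geom.acetab_mask)
    meta = {
        "grid_shape": [int(s) for s in geom.grid_shape],
        "head_center": [float(v) for v in geom.head_center],
        "reference_angle_deg": float(geom.reference_angle_deg),
        "femur_mask": "femur_mask.nii",
        "acetab_mask": "acetab_mask.nii",
    }
    out = directory / "atlas.yaml"
    out.write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_atlas(path) -> AtlasGeometry:
    path = Path(path)
    directory = path.parent if path.is_file() else path
    meta = yaml.safe_load((directory / "atlas.yaml").read_text())
    femur, _ = read_volume(directory / meta["femur_mask"])
    acetab, _ = read_volume(directory / meta["acetab_mask"])
    return AtlasGeometry(
        grid_shape=tuple(meta["grid_shape"]),
        head_center=tuple(meta["head_center"]),
        reference_angle_deg=meta["reference_angle_deg"],
        femur_mask=np.asarray(femur, dtype=bool),
        acetab_mask=np.asarray(acetab, dtype=bool),
    )


def write_group_stats(prefix, stats) -> dict[str, Path]:
    """Persist group statistics as paired volumes plus JSON metadata
    ``{scope, n}`` under ``<prefix>_mean.nii`` / ``<prefix>_sd.nii`` /
    ``<prefix>_usable.nii`` / ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "mean": write_volume(prefix.parent / f"{prefix.name}_mean.nii", stats.mean_map),
        "sd": write_volume(prefix.parent / f"{prefix.name}_sd.nii", stats.sd_map),
        "usable": write_volume(prefix.parent / f"{prefix.name}_usable.nii", stats.usable),
    }
    meta_path = prefix.parent / f"{prefix.name}.json"
    meta_path.write_text(json.dumps({"scope": stats.scope.value, "n": stats.n}, sort_keys=True, indent=1) + "\n")
    paths["meta"] = meta_path
    return paths


def read_group_stats(prefix):
    from .calibration import GroupStats, StatsScope

    prefix = Path(prefix)
    meta_path = prefix.parent / f"{prefix.name}.json"
    if not meta_path.exists():
        raise InputError(f"missing group-stats sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    mean, _ = read_volume(prefix.parent / f"{prefix.name}_mean.nii")
    sd, _ = read_volume(prefix.parent / f"{prefix.name}_sd.nii")
    usable, _ = read_volume(prefix.parent / f"{prefix.name}_usable.nii")
    return GroupStats(
        np.asarray(mean, dtype=float), np.asarray(sd, dtype=float),
        np.asarray(usable, dtype=bool), int(meta["n"]), StatsScope(meta["scope"]),
    )


def write_labels(path, labels: SubregionLabels) -> Path:
    """Write the wedge label grid as an integer NIfTI volume (retained sets go in the
    pipeline manifest, not the image)."""
    return write_volume(path, labels.labels.astype(np.int16))


def read_labels(path) -> np.ndarray:
    arr, _ = read_volume(path)
    return np.asarray(arr, dtype=np.int16)
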