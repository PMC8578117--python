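"""Readers/writers and run manifests.

NIfTI is the interchange format for images, parameter maps and deformation
fields (float32 on disk; all computation in float64); AIFs travel as
two-column CSV (time_s, concentration) with a header row; configurations as
YAML/JSON. Every registration run writes a manifest sufficient to reproduce
it: input paths, the default-filled configuration, package version,
timestamps and per-level iteration counts.

Axis convention: arrays are stored as (x, y[, z], t); a 3-dimensional file
is a single-slice dynamic series unless `multislice` is requested, in which
case each z-slice becomes its own series.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import AIF, DynamicSeries
from .model import MDRConfig, MDRResults

__all__ = [
    "read_series",
    "write_series",
    "read_aif",
    "write_aif",
    "write_maps",
    "read_maps",
    "write_fields",
    "read_fields",
    "write_result",
    "load_config",
    "write_config",
]


def _affine(voxel_dims) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(np.atleast_1d(voxel_dims)[:3]):
        aff[i, i] = v
    return aff


def write_series(series: DynamicSeries, path) -> Path:
    """Write a dynamic series as a float32 NIfTI (*spatial, t)."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32),
                          _affine(series.voxel_dims))
    img.header["pixdim"][4] = series.frame_dt
    nib.save(img, path)
    return path


def read_series(path, frame_dt: float | None = None, n0: int = 1,
                multislice: bool = False):
    """Read a dynamic series from NIfTI.

    Frame timing is taken from `frame_dt` or, failing that, the header's
    pixdim[4]; an error demands `frame_dt` when neither is available. With
    `multislice=True` a 4D file is split into one 2D series per z-slice.
    Frame times are acquisition mid-points, (k + 1/2) * frame_dt.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError("expected a NIfTI file with 3 or 4 dimensions")
    if frame_dt is None:
        frame_dt = float(img.header["pixdim"][4])
        if frame_dt <= 0:
            raise ValueError("no frame timing in header; pass frame_dt")
    voxel_dims = np.abs(np.diag(img.affine))[: data.ndim - 1]
    K = data.shape[-1]
    times = (np.arange(K) + 0.5) * frame_dt

    def mk(arr, vd):
        return DynamicSeries(arr, voxel_dims=vd, frame_times=times, n0=n0)

    if data.ndim == 4 and multislice:
        return [mk(data[:, :, z, :], voxel_dims[:2]) for z in range(data.shape[2])]
    return mk(data, voxel_dims)


def write_aif(aif: AIF, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": aif.times, "concentration": aif.values}
                 ).to_csv(path, index=False)
    return path


def read_aif(path, baseline_duration: float | None = None) -> AIF:
    """Read a two-column (time_s, concentration) CSV with a header row."""
    df = pd.read_csv(path)
    for col in ("time_s", "concentration"):
        if col not in df.columns:
            raise ValueError(f"AIF CSV must contain a '{col}' column")
    values = df["concentration"].to_numpy(dtype=float)
    if baseline_duration is None:
        nz = np.nonzero(values)[0]
        times = df["time_s"].to_numpy(dtype=float)
        baseline_duration = float(times[nz[0]]) if nz.size else 0.0
    return AIF(df["time_s"].to_numpy(dtype=float), values, baseline_duration)


def write_maps(maps: dict, outdir, prefix: str = "map",
               voxel_dims=1.0) -> dict:
    """One float32 NIfTI volume per parameter map; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in maps.items():
        p = outdir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32),
                                 _affine(voxel_dims)), p)
        paths[name] = p
    return paths


def read_maps(outdir, prefix: str = "map") -> dict:
    outdir = Path(outdir)
    maps = {}
    for p in sorted(outdir.glob(f"{prefix}_*.nii.gz")):
        name = p.name[len(prefix) + 1:].replace(".nii.gz", "")
        maps[name] = np.asarray(nib.load(str(p)).dataobj, dtype=np.float32)
    return maps


def write_fields(fields: np.ndarray, path, spacing=None) -> Path:
    """Deformation fields (n_frames, *spatial, d) as a 5D NIfTI vector stack
    (*spatial, d, n_frames) plus a JSON sidecar with the grid description."""
    path = Path(path)
    fields = np.asarray(fields, dtype=np.float32)
    arr = np.moveaxis(fields, 0, -1)          # (*spatial, d, K)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), path)
    side = {"axes": "(spatial..., component, frame)",
            "n_frames": int(fields.shape[0]),
            "ndim": int(fields.shape[-1])}
    if spacing is not None:
        side["control_spacing_px"] = [float(s) for s in np.atleast_1d(spacing)]
        side["origin"] = [0.0] * int(fields.shape[-1])
    Path(str(path) + ".json").write_text(json.dumps(side, indent=2))
    return path


def read_fields(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.moveaxis(arr, -1, 0)


def write_config(config: MDRConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict()))
    return path


def load_config(path) -> MDRConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if "grid_spacing_min" in d and isinstance(d["grid_spacing_min"], list):
        d["grid_spacing_min"] = tuple(d["grid_spacing_min"])
    if "frame_order" in d and d["frame_order"] is not None:
        d["frame_order"] = tuple(d["frame_order"])
    return MDRConfig(**d)


def write_result(result: MDRResults, outdir, inputs: dict | None = None) -> dict:
    """Write a complete registration result.

    Emits the corrected series, one NIfTI per parameter map, the deformation
    fields with their JSON sidecar, the cost trace as CSV and a run manifest;
    filenames are deterministic. Returns name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["corrected"] = write_series(result.corrected, outdir / "corrected.nii.gz")
    paths.update(write_maps(result.params, outdir,
                            voxel_dims=result.corrected.voxel_dims))
    paths["fields"] = write_fields(result.deformation_fields(),
                                   outdir / "deformation_fields.nii.gz",
                                   spacing=result.grid.spacing)
    trace_path = outdir / "cost_trace.csv"
    result.cost_trace.to_csv(trace_path, index=False)
    paths["cost_trace"] = trace_path

    per_level = (result.cost_trace[result.cost_trace.step == "deform"]
                 .groupby("level").size().to_dict())
    manifest = {
        "package": "renalmdr",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {k: str(v) for k, v in (inputs or {}).items()},
        "config": result.model.config.to_dict(),
        "n0": int(result.model.n0),
        "iterations_per_level": {int(k): int(v) for k, v in per_level.items()},
        "final_chi2": result.chi2,
        "cost_trace": trace_path.name,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mpath
    return paths
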