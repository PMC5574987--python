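"""File formats: NIfTI image series and maps, TIFF qPLM maps, YAML specs.

An image series is stored as ``<base>.nii`` (rows x cols x 1 x n_prep),
``<base>_inv.nii`` for the inversion-prepared twin where present,
``<base>_mask.nii`` (0 = outside, 1 = tissue, 2 = noise background) and
a ``<base>.json`` sidecar holding the acquisition schedule and sample
orientation.  qPLM maps are single-channel 32-bit float TIFFs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .phantom import (
    AcquisitionSchedule,
    ImageSeries,
    PhantomSpec,
    PLMMaps,
    RelaxParams,
)
from .relaxfit import RelaxMap

__all__ = [
    "write_series",
    "read_series",
    "write_map",
    "read_map",
    "write_plm_maps",
    "read_plm_maps",
    "save_phantom_spec",
    "load_phantom_spec",
]


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))


def _stack_to_nifti(stack: np.ndarray) -> nib.Nifti1Image:
    # (nt, rows, cols) -> (rows, cols, 1, nt)
    return _nifti(np.transpose(stack, (1, 2, 0))[:, :, None, :])


def _nifti_to_stack(img) -> np.ndarray:
    arr = np.asarray(img.dataobj, dtype=float)
    return np.transpose(arr[:, :, 0, :], (2, 0, 1))


def write_series(series: ImageSeries, base) -> Path:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_stack_to_nifti(series.data), str(base) + ".nii")
    if series.data_inverted is not None:
        nib.save(_stack_to_nifti(series.data_inverted), str(base) + "_inv.nii")
    labels = series.mask.astype(np.int16) + 2 * series.background_roi.astype(np.int16)
    nib.save(nib.Nifti1Image(labels, np.eye(4)), str(base) + "_mask.nii")
    sched = dataclasses.asdict(series.schedule)
    meta = {"schedule": sched, "sample_orientation_deg": series.sample_orientation_deg}
    Path(str(base) + ".json").write_text(json.dumps(meta, indent=2))
    return base


def read_series(base) -> ImageSeries:
    base = Path(base)
    meta = json.loads(Path(str(base) + ".json").read_text())
    s = meta["schedule"]
    schedule = AcquisitionSchedule(
        parameter_kind=s["parameter_kind"],
        prep_times_ms=tuple(s["prep_times_ms"]),
        spinlock_amplitude_hz=s.get("spinlock_amplitude_hz"),
        pulse_duration_ms=s.get("pulse_duration_ms"),
        n_pulses=tuple(s["n_pulses"]) if s.get("n_pulses") else None,
        has_inversion_pair=s.get("has_inversion_pair", False),
    )
    data = _nifti_to_stack(nib.load(str(base) + ".nii"))
    inv_path = Path(str(base) + "_inv.nii")
    inv = _nifti_to_stack(nib.load(str(inv_path))) if inv_path.exists() else None
    labels = np.asarray(nib.load(str(base) + "_mask.nii").dataobj)
    return ImageSeries(
        data=data,
        schedule=schedule,
        sample_orientation_deg=float(meta["sample_orientation_deg"]),
        mask=labels == 1,
        background_roi=labels == 2,
        data_inverted=inv,
    )


def write_map(relax_map: RelaxMap, base, diagnostics_csv: bool = False) -> Path:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_nifti(relax_map.times_ms), str(base) + "_time.nii")
    nib.save(
        nib.Nifti1Image(relax_map.converged.astype(np.int16), np.eye(4)),
        str(base) + "_converged.nii",
    )
    meta = {
        "parameter_kind": relax_map.parameter_kind,
        "sample_orientation_deg": relax_map.sample_orientation_deg,
    }
    Path(str(base) + ".json").write_text(json.dumps(meta, indent=2))
    if diagnostics_csv:
        import pandas as pd

        r, c = np.nonzero(relax_map.mask)
        pd.DataFrame(
            {
                "row": r,
                "col": c,
                "time_ms": relax_map.times_ms[r, c],
                "amplitude": relax_map.amplitude[r, c],
                "baseline": relax_map.baseline[r, c],
                "rss": relax_map.rss[r, c],
                "converged": relax_map.converged[r, c],
            }
        ).to_csv(str(base) + "_diagnostics.csv", index=False, float_format="%.6g")
    return base


def read_map(base) -> RelaxMap:
    base = Path(base)
    meta = json.loads(Path(str(base) + ".json").read_text())
    times = np.asarray(nib.load(str(base) + "_time.nii").dataobj, dtype=float)
    conv = np.asarray(nib.load(str(base) + "_converged.nii").dataobj) > 0
    mask = np.isfinite(times)
    nanlike = np.full_like(times, np.nan)
    return RelaxMap(
        times_ms=times,
        amplitude=nanlike.copy(),
        baseline=nanlike.copy(),
        rss=nanlike.copy(),
        converged=conv,
        mask=mask,
        parameter_kind=meta["parameter_kind"],
        sample_orientation_deg=float(meta["sample_orientation_deg"]),
    )


def write_plm_maps(maps: PLMMaps, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "orientation.tif", maps.orientation.astype(np.float32))
    tifffile.imwrite(directory / "retardation.tif", maps.retardation.astype(np.float32))
    tifffile.imwrite(directory / "mask.tif", maps.mask.astype(np.uint8))
    return directory


def read_plm_maps(directory, pixel_size_um: float = 2.53) -> PLMMaps:
    directory = Path(directory)
    return PLMMaps(
        orientation=tifffile.imread(directory / "orientation.tif").astype(float),
        retardation=tifffile.imread(directory / "retardation.tif").astype(float),
        mask=tifffile.imread(directory / "mask.tif").astype(bool),
        pixel_size_um=pixel_size_um,
    )


def save_phantom_spec(spec: PhantomSpec, path) -> Path:
    d = dataclasses.asdict(spec)
    d["relax_params"] = {k: dataclasses.asdict(v) for k, v in spec.relax_params.items()}
    d["image_shape"] = list(spec.image_shape)
    d["dispersion_deg"] = list(spec.dispersion_deg)
    path = Path(path)
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def load_phantom_spec(path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["image_shape"] = tuple(d["image_shape"])
    d["dispersion_deg"] = tuple(d["dispersion_deg"])
    d["relax_params"] = {k: RelaxParams(**v) for k, v in d["relax_params"].items()}
    return PhantomSpec(**d)
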