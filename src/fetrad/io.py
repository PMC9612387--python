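"""On-disk formats: NIfTI volumes, JSON sidecars, CSV tables, run config.

Volumes are NIfTI (.nii/.nii.gz) via nibabel; NIfTI has no standard slot for
frame timing, so the schedule travels as a JSON sidecar
``{"frame_starts_s": [...], "frame_durations_s": [...]}``. Tables are
RFC-4180 CSV (UTF-8, '.' decimal); reports are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .classify import ClassificationConfig
from .maps import DynamicImage, ParametricImage
from .phantom import SyntheticPatient
from .schedule import FrameSchedule

__all__ = [
    "read_dynamic",
    "write_dynamic",
    "read_mask",
    "write_mask",
    "write_parametric",
    "write_patient",
    "RunConfig",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def write_dynamic(dynamic: DynamicImage, path_image, path_schedule) -> None:
    affine = dynamic.affine if dynamic.affine is not None else _affine(dynamic.voxel_size_mm)
    nib.save(nib.Nifti1Image(dynamic.voxels, affine), str(path_image))
    Path(path_schedule).write_text(json.dumps(dynamic.schedule.to_dict()))


def read_dynamic(path_image, path_schedule) -> DynamicImage:
    """Load a 4D dynamic volume plus its frame-timing sidecar."""
    img = nib.load(str(path_image))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D dynamic image, got {data.ndim}D")
    schedule = FrameSchedule.from_dict(json.loads(Path(path_schedule).read_text()))
    if data.shape[-1] != schedule.n_frames:
        raise ValueError(
            f"image has {data.shape[-1]} frames but schedule lists {schedule.n_frames}"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(data, schedule, voxel_size_mm=voxel_size, affine=img.affine)


def write_mask(mask: np.ndarray, path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(voxel_size_mm)),
        str(path),
    )


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_parametric(image: ParametricImage, path) -> None:
    affine = image.affine if image.affine is not None else _affine(image.voxel_size_mm)
    nib.save(nib.Nifti1Image(image.voxels.astype(float), affine), str(path))


def write_patient(patient: SyntheticPatient, out_dir) -> None:
    """Write one synthetic patient: 4D image, schedule, masks, truth parameters."""
    out = Path(out_dir) / patient.patient_id
    out.mkdir(parents=True, exist_ok=True)
    write_dynamic(patient.dynamic_image, out / "dynamic.nii.gz", out / "schedule.json")
    vs = patient.dynamic_image.voxel_size_mm
    for name, mask in patient.voi_set.masks().items():
        write_mask(mask, out / f"mask_{name}.nii.gz", vs)
    truth = {
        "patient_id": patient.patient_id,
        "phenotype": patient.phenotype,
        "seed": patient.seed,
        "kinetics": {k: dataclasses.asdict(v) for k, v in patient.truth.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run.

    Round-trips losslessly through JSON; every run writes the resolved config
    next to its outputs, and every output table carries ``config_hash`` so
    tables from different runs cannot be mixed silently.
    """

    out_dir: str = "fetrad_run"
    n_patients: int = 46
    isometabolic_fraction: float = 29 / 46
    base_seed: int = 0
    noise_scale: float = 0.05
    bin_count: int = 32
    ttp_smoothing: int | None = None
    alpha: float = 0.05
    n_repeats: int = 50
    n_folds: int = 5
    inner_folds: int = 5
    c_grid: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))
    group_by_patient: bool = False
    run_univariate: bool = False
    log_level: str = "INFO"

    def classification_config(self) -> ClassificationConfig:
        return ClassificationConfig(
            n_repeats=self.n_repeats,
            n_folds=self.n_folds,
            inner_folds=self.inner_folds,
            C_grid=tuple(self.c_grid),
            seed=self.base_seed,
            group_by_patient=self.group_by_patient,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["c_grid"] = list(d["c_grid"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["c_grid"] = tuple(d["c_grid"])
        return cls(**d)

    def hash(self) -> str:
        """Digest of the analysis-defining fields (where outputs go is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        d["c_grid"] = list(d["c_grid"])
        text = json.dumps(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
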