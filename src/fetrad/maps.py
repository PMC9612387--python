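"""Parametric images from dynamic PET: TBR summation images and TTP maps.

Three parametric images are derived per patient:

* ``TBR_5_15``  — early 5–15 min p.i. summation image, crescent-normalized;
* ``TBR_20_40`` — standard 20–40 min p.i. summation image, crescent-normalized;
* ``TTP``      — per-voxel time-to-peak of the time-activity curve, minutes.

Summation images are duration-weighted frame means (not raw sums), so TBR is
independent of how the window is split into frames. A frame belongs to a
window when its mid-time lies in [t_start, t_end). TTP is reported at frame
mid-times with the earliest frame winning ties; no sub-frame interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import FrameSchedule

__all__ = [
    "DynamicImage",
    "ParametricImage",
    "sum_frames",
    "tbr_normalize",
    "ttp_map",
    "compute_parametric_maps",
    "IMAGE_KINDS",
]

IMAGE_KINDS = ("TBR_5_15", "TBR_20_40", "TTP")

#: Quantification windows in minutes p.i. (end clipped to the acquisition).
WINDOWS_MIN = {"TBR_5_15": (5.0, 15.0), "TBR_20_40": (20.0, 40.0)}


@dataclass
class DynamicImage:
    """4D activity volume (x, y, z, frame) with its frame schedule."""

    voxels: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("dynamic image must be 4D (x, y, z, frame)")
        if self.voxels.shape[-1] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis ({self.voxels.shape[-1]}) does not match "
                f"schedule ({self.schedule.n_frames} frames)"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("dynamic image contains non-finite activity values")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class ParametricImage:
    """3D parametric map with a kind tag.

    TBR kinds are dimensionless ratios (>= 0); TTP is in minutes p.i. and
    takes values only at the frame mid-times of the schedule.
    """

    voxels: np.ndarray
    kind: str
    units: str = ""
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in IMAGE_KINDS:
            raise ValueError(f"unknown parametric kind {self.kind!r}")
        if not self.units:
            self.units = "min" if self.kind == "TTP" else "ratio"


def _frames_in_window(schedule: FrameSchedule, window_min) -> np.ndarray:
    t0, t1 = float(window_min[0]), float(window_min[1])
    mids = schedule.mid_times_min
    sel = np.nonzero((mids >= t0) & (mids < t1))[0]
    if sel.size == 0:
        raise ValueError(f"no frame mid-time falls in window [{t0}, {t1}) min")
    return sel


def sum_frames(dynamic: DynamicImage, window_min) -> np.ndarray:
    """Duration-weighted mean image over the frames whose mid-time is in the window.

    ``window_min`` is (t_start, t_end) in minutes p.i.; frames are selected by
    mid-time in [t_start, t_end).
    """
    sel = _frames_in_window(dynamic.schedule, window_min)
    durs = np.asarray(dynamic.schedule.frame_durations)[sel]
    frames = dynamic.voxels[..., sel]
    return np.tensordot(frames, durs, axes=([-1], [0])) / durs.sum()


def tbr_normalize(
    static_image: np.ndarray,
    crescent_mask: np.ndarray,
    kind: str,
    voxel_size_mm=(3.0, 3.0, 3.0),
    affine=None,
) -> ParametricImage:
    """Divide a summation image by its mean over the crescent background VOI."""
    crescent = np.asarray(crescent_mask) > 0
    if not crescent.any():
        raise ValueError("crescent mask is empty")
    ref = float(np.mean(static_image[crescent]))
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"crescent mean must be finite and > 0, got {ref}")
    return ParametricImage(
        np.asarray(static_image, dtype=float) / ref,
        kind=kind,
        voxel_size_mm=tuple(voxel_size_mm),
        affine=affine,
    )


def ttp_map(dynamic: DynamicImage, smoothing_window: int | None = None) -> ParametricImage:
    """Per-voxel time-to-peak (minutes p.i., at frame mid-times).

    The TAC may optionally be smoothed with a centred moving average over
    ``smoothing_window`` frames (odd; the window shrinks at the edges) before
    locating the peak. The first frame attaining the maximum wins ties.
    """
    if dynamic.schedule.n_frames < 3:
        raise ValueError("TTP needs at least 3 frames")
    tacs = dynamic.voxels
    if smoothing_window is not None:
        if smoothing_window % 2 == 0 or smoothing_window < 1:
            raise ValueError("smoothing_window must be odd and >= 1")
        half = smoothing_window // 2
        n = tacs.shape[-1]
        # cumulative-sum moving average with shrinking edge windows
        csum = np.concatenate(
            [np.zeros(tacs.shape[:-1] + (1,)), np.cumsum(tacs, axis=-1)], axis=-1
        )
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        tacs = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    peak_idx = np.argmax(tacs, axis=-1)  # argmax returns the first maximum
    mids = dynamic.schedule.mid_times_min
    return ParametricImage(
        mids[peak_idx],
        kind="TTP",
        voxel_size_mm=dynamic.voxel_size_mm,
        affine=dynamic.affine,
    )


def compute_parametric_maps(
    dynamic: DynamicImage,
    crescent_mask: np.ndarray,
    smoothing_window: int | None = None,
) -> dict[str, ParametricImage]:
    """All three parametric images for one patient, keyed by kind."""
    out: dict[str, ParametricImage] = {}
    for kind, window in WINDOWS_MIN.items():
        static = sum_frames(dynamic, window)
        out[kind] = tbr_normalize(
            static, crescent_mask, kind, dynamic.voxel_size_mm, dynamic.affine
        )
    out["TTP"] = ttp_map(dynamic, smoothing_window)
    return out
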