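"""Volumes of interest: tumor, mirrored contralateral background, crescent.

The tumor VOI is compared against its own reflection into the contralateral
hemisphere (ventricle voxels removed), which gives a shape-matched healthy
reference region for radiomic comparison. A separate crescent-shaped VOI in
the contralateral hemisphere provides the normalization mean for TBR images.

Reflection is a pure index flip about a stated mid-sagittal voxel plane along
axis 0; no registration to a symmetry template is attempted. This is exact
for the symmetric synthetic phantoms used here and is a documented
approximation for real, asymmetric anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VOISet", "mirror_mask", "validate_voi_set"]


@dataclass
class VOISet:
    """The binary masks used per patient, all on the same voxel grid.

    ``midsagittal_index`` is the reflection plane along axis 0 in voxel
    coordinates; it may be half-integer (between two voxel columns), in which
    case the flip maps index x to ``2*midsagittal_index - x`` which is again
    an integer.
    """

    tumor_mask: np.ndarray
    mirrored_mask: np.ndarray
    crescent_mask: np.ndarray
    ventricle_mask: np.ndarray
    midsagittal_index: float

    def __post_init__(self) -> None:
        shapes = {
            m.shape
            for m in (self.tumor_mask, self.mirrored_mask, self.crescent_mask, self.ventricle_mask)
        }
        if len(shapes) != 1:
            raise ValueError("all masks must share one grid shape")

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "tumor": self.tumor_mask,
            "mirrored": self.mirrored_mask,
            "crescent": self.crescent_mask,
            "ventricle": self.ventricle_mask,
        }


def _reflect_indices(x: np.ndarray, midsagittal_index: float) -> np.ndarray:
    ref = 2.0 * midsagittal_index - x
    ref_int = np.rint(ref).astype(int)
    if not np.allclose(ref, ref_int):
        raise ValueError("midsagittal_index must be integer or half-integer")
    return ref_int

def mirror_mask(
    tumor_mask: np.ndarray,
    midsagittal_index: float,
    exclusion_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Reflect a tumor mask about the mid-sagittal plane, minus excluded voxels.

    Parameters
    ----------
    tumor_mask : 3D bool/int array
        Must lie entirely on one side of the plane.
    midsagittal_index : float
        Reflection plane along axis 0 (voxel coordinates).
    exclusion_mask : 3D array, optional
        Voxels (typically ventricle) removed from the reflected mask.

    Returns
    -------
    mirrored : 3D bool array
    n_excluded : int
        Number of reflected voxels removed by the exclusion mask.

    Raises
    ------
    ValueError
        If the tumor touches or crosses the mid-plane, the reflection leaves
        the grid, or the result is empty after exclusion.
    """
    tumor = np.asarray(tumor_mask) > 0
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    xs, ys, zs = np.nonzero(tumor)
    side = np.sign(xs - midsagittal_index)
    if np.any(side == 0) or len(np.unique(side)) != 1:
        raise ValueError("tumor mask touches or crosses the mid-sagittal plane")
    rx = _reflect_indices(xs, midsagittal_index)
    if rx.min() < 0 or rx.max() >= tumor.shape[0]:
        raise ValueError("reflected mask falls outside the grid")
    mirrored = np.zeros_like(tumor)
    mirrored[rx, ys, zs] = True
    n_excluded = 0
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask) > 0
        n_excluded = int(np.count_nonzero(mirrored & excl))
        mirrored &= ~excl
    if not mirrored.any():
        raise ValueError("mirrored mask empty after exclusion")
    return mirrored, n_excluded


def validate_voi_set(voi_set: VOISet) -> list[str]:
    """Check the VOISet invariants; return a list of violations (empty if valid)."""
    violations: list[str] = []
    masks = {k: np.asarray(v) > 0 for k, v in voi_set.masks().items()}
    for name in ("tumor", "mirrored", "crescent"):
        if not masks[name].any():
            violations.append(f"{name} mask is empty")
    if (masks["tumor"] & masks["mirrored"]).any():
        violations.append("tumor and mirrored masks are not disjoint")
    if (masks["mirrored"] & masks["ventricle"]).any():
        violations.append("mirrored mask overlaps the ventricle mask")
    return violations
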