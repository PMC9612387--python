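"""Gray-level discretization of in-mask intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationConfig", "discretize"]


@dataclass(frozen=True)
class DiscretizationConfig:
    """How continuous intensities are binned into gray levels.

    ``fixed_bin_count`` spans [min, max] of the in-mask intensities with
    ``bin_count`` equal-width levels (default 32 — TBR images are O(1) ratios
    and TTP takes at most one value per frame, so a fixed absolute width tuned
    to SUV/CT scales would collapse the histogram). ``fixed_bin_width``
    assigns level floor((x - min) / bin_width) + 1.
    """

    mode: str = "fixed_bin_count"
    bin_count: int = 32
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")
        if self.mode == "fixed_bin_width" and (self.bin_width is None or self.bin_width <= 0):
            raise ValueError("bin_width must be > 0")


def discretize(
    image: np.ndarray, mask: np.ndarray, config: DiscretizationConfig
) -> tuple[np.ndarray, int, bool]:
    """Discretize in-mask intensities to integer gray levels 1..Ng.

    Returns
    -------
    levels : int array, full grid
        Gray level per voxel, 0 outside the mask.
    n_levels : int
    degenerate : bool
        True when the in-mask image is constant (single level 1).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(image, dtype=float)[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities inside the mask")
    mn, mx = float(vals.min()), float(vals.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if mx == mn:
        levels[mask] = 1
        return levels, 1, True
    if config.mode == "fixed_bin_count":
        lev = np.floor((vals - mn) / (mx - mn) * config.bin_count).astype(np.int32) + 1
        lev = np.minimum(lev, config.bin_count)  # x == max lands in the top bin
        n_levels = config.bin_count
    else:
        lev = np.floor((vals - mn) / config.bin_width).astype(np.int32) + 1
        n_levels = int(lev.max())
    levels[mask] = lev
    return levels, n_levels, False
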