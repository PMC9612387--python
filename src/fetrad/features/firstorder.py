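"""The 18 default first-order (intensity) features.

Computed on the raw in-mask intensities, except Entropy and Uniformity which
use the discretized gray-level histogram. Variance/skewness/kurtosis are
population moments; kurtosis is not excess-corrected (a normal distribution
scores 3). Percentiles use linear interpolation. Skewness and kurtosis of a
constant region are returned as 0 and flagged degenerate.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationConfig, discretize

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    image: np.ndarray,
    mask: np.ndarray,
    config: DiscretizationConfig | None = None,
    voxel_volume: float = 1.0,
) -> tuple[dict[str, float], set[str]]:
    """Return the 18 first-order feature values and the degenerate-flag set."""
    config = config or DiscretizationConfig()
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(image, dtype=float)[mask]
    n = x.size
    flags: set[str] = set()

    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew = kurt = 0.0
        flags.update({"Skewness", "Kurtosis"})

    levels, n_levels, degenerate = discretize(image, mask, config)
    p = np.bincount(levels[mask], minlength=n_levels + 1)[1:] / n
    nz = p[p > 0]
    if degenerate:
        flags.update({"Entropy", "Uniformity"})

    energy = float(np.sum(x**2))
    values = {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
    return values, flags
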