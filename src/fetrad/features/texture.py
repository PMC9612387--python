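"""The 75 default texture features evaluated from the five matrix families.

GLCM (24) and GLRLM (16) features are computed per direction and averaged
over the 13 unique 3D directions; directions with no voxel pairs are skipped.
GLSZM (16), GLDM (14) and NGTDM (5) use isotropic neighborhoods and need no
aggregation. Degenerate conventions for single-gray-level VOIs (correlation-
type GLCM features = 1, entropies = 0, ...) are flagged, not errors.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationConfig, discretize
from .matrices import (
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_stats,
)

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "texture_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "gldm_features_from_matrix",
    "ngtdm_features",
    "ngtdm_features_from_stats",
]

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)
GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _glcm_features_single(counts: np.ndarray, n_levels: int) -> dict[str, float] | None:
    total = counts.sum()
    if total == 0:
        return None
    p = counts / total
    ng = n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sigx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    ks = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(ks.size)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    kd = np.arange(0, ng)
    p_diff = np.zeros(kd.size)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    hx = _entropy2(px)
    hy = _entropy2(py)
    hxy = _entropy2(p)
    pxpy = np.outer(px, py)
    joint_nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[joint_nz] * np.log2(pxpy[joint_nz])).sum())
    hxy2 = _entropy2(pxpy)

    da = float((kd * p_diff).sum())
    corr = 1.0 if sigx * sigy == 0 else float(((ii * jj * p).sum() - ux * uy) / (sigx * sigy))
    imc1 = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: second largest eigenvalue of Q over levels with mass
    live = px > 0
    if live.sum() < 2:
        mcc = 1.0
    else:
        psub = p[np.ix_(live, live)]
        q = (psub / px[live, None]) @ (psub / py[live][None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(ev[1], 0.0)))

    offdiag = ii != jj
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float((((ii + jj) - ux - uy) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - ux - uy) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - ux - uy) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(((kd - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum()),
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float(((ii - ux) ** 2 * p).sum()),
    }


def glcm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    per_dir = [
        f
        for counts in glcm_matrices(levels, n_levels)
        if (f := _glcm_features_single(counts, n_levels)) is not None
    ]
    if not per_dir:
        raise ValueError("no voxel pairs in any direction (mask too small)")
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES}


def _sized_matrix_features(
    pmat: np.ndarray, n_voxels: int, kind: str
) -> dict[str, float]:
    """Shared feature formulas for GLRLM/GLSZM-style (gray level × size) matrices."""
    ns = pmat.sum()
    i = np.arange(1, pmat.shape[0] + 1, dtype=float)
    j = np.arange(1, pmat.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = pmat / ns
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    pg = pmat.sum(axis=1)  # per gray level
    ps = pmat.sum(axis=0)  # per size
    base = {
        "SmallEmphasis": float((pmat / jj**2).sum() / ns),
        "LargeEmphasis": float((pmat * jj**2).sum() / ns),
        "GrayLevelNonUniformity": float((pg**2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / ns**2),
        "SizeNonUniformity": float((ps**2).sum() / ns),
        "SizeNonUniformityNormalized": float((ps**2).sum() / ns**2),
        "Percentage": float(ns / n_voxels),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "SizeVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "Entropy": _entropy2(p.ravel()),
        "LowGrayLevelEmphasis": float((pmat / ii**2).sum() / ns),
        "HighGrayLevelEmphasis": float((pmat * ii**2).sum() / ns),
        "SmallLowGrayLevelEmphasis": float((pmat / (ii**2 * jj**2)).sum() / ns),
        "SmallHighGrayLevelEmphasis": float((pmat * ii**2 / jj**2).sum() / ns),
        "LargeLowGrayLevelEmphasis": float((pmat * jj**2 / ii**2).sum() / ns),
        "LargeHighGrayLevelEmphasis": float((pmat * ii**2 * jj**2).sum() / ns),
    }
    if kind == "glrlm":
        return {
            "GrayLevelNonUniformity": base["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": base["GrayLevelNonUniformityNormalized"],
            "GrayLevelVariance": base["GrayLevelVariance"],
            "HighGrayLevelRunEmphasis": base["HighGrayLevelEmphasis"],
            "LongRunEmphasis": base["LargeEmphasis"],
            "LongRunHighGrayLevelEmphasis": base["LargeHighGrayLevelEmphasis"],
            "LongRunLowGrayLevelEmphasis": base["LargeLowGrayLevelEmphasis"],
            "LowGrayLevelRunEmphasis": base["LowGrayLevelEmphasis"],
            "RunEntropy": base["Entropy"],
            "RunLengthNonUniformity": base["SizeNonUniformity"],
            "RunLengthNonUniformityNormalized": base["SizeNonUniformityNormalized"],
            "RunPercentage": base["Percentage"],
            "RunVariance": base["SizeVariance"],
            "ShortRunEmphasis": base["SmallEmphasis"],
            "ShortRunHighGrayLevelEmphasis": base["SmallHighGrayLevelEmphasis"],
            "ShortRunLowGrayLevelEmphasis": base["SmallLowGrayLevelEmphasis"],
        }
    return {
        "GrayLevelNonUniformity": base["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": base["GrayLevelNonUniformityNormalized"],
        "GrayLevelVariance": base["GrayLevelVariance"],
        "HighGrayLevelZoneEmphasis": base["HighGrayLevelEmphasis"],
        "LargeAreaEmphasis": base["LargeEmphasis"],
        "LargeAreaHighGrayLevelEmphasis": base["LargeHighGrayLevelEmphasis"],
        "LargeAreaLowGrayLevelEmphasis": base["LargeLowGrayLevelEmphasis"],
        "LowGrayLevelZoneEmphasis": base["LowGrayLevelEmphasis"],
        "SizeZoneNonUniformity": base["SizeNonUniformity"],
        "SizeZoneNonUniformityNormalized": base["SizeNonUniformityNormalized"],
        "SmallAreaEmphasis": base["SmallEmphasis"],
        "SmallAreaHighGrayLevelEmphasis": base["SmallHighGrayLevelEmphasis"],
        "SmallAreaLowGrayLevelEmphasis": base["SmallLowGrayLevelEmphasis"],
        "ZoneEntropy": base["Entropy"],
        "ZonePercentage": base["Percentage"],
        "ZoneVariance": base["SizeVariance"],
    }


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_voxels = int(np.count_nonzero(levels))
    per_dir = [
        _sized_matrix_features(m, n_voxels, "glrlm")
        for m in glrlm_matrices(levels, n_levels)
    ]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


def glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_voxels = int(np.count_nonzero(levels))
    return _sized_matrix_features(glszm_matrix(levels, n_levels), n_voxels, "glszm")


def gldm_features(levels: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    return gldm_features_from_matrix(gldm_matrix(levels, n_levels, alpha))


def gldm_features_from_matrix(pmat: np.ndarray) -> dict[str, float]:
    nz = pmat.sum()
    i = np.arange(1, pmat.shape[0] + 1, dtype=float)
    j = np.arange(1, pmat.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = pmat / nz
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    pg = pmat.sum(axis=1)
    pd = pmat.sum(axis=0)
    return {
        "DependenceEntropy": _entropy2(p.ravel()),
        "DependenceNonUniformity": float((pd**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz**2),
        "DependenceVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "HighGrayLevelEmphasis": float((pmat * ii**2).sum() / nz),
        "LargeDependenceEmphasis": float((pmat * jj**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((pmat * ii**2 * jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((pmat * jj**2 / ii**2).sum() / nz),
        "LowGrayLevelEmphasis": float((pmat / ii**2).sum() / nz),
        "SmallDependenceEmphasis": float((pmat / jj**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((pmat * ii**2 / jj**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((pmat / (ii**2 * jj**2)).sum() / nz),
    }


def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    s, n = ngtdm_stats(levels, n_levels)
    return ngtdm_features_from_stats(s, n, n_levels)


def ngtdm_features_from_stats(s: np.ndarray, n: np.ndarray, n_levels: int) -> dict[str, float]:
    n_total = n.sum()
    if n_total == 0:
        raise ValueError("no voxel has an in-mask neighbor")
    p = n / n_total
    i = np.arange(1, n_levels + 1, dtype=float)
    live = p > 0
    ngp = int(live.sum())
    ps = float((p * s).sum())

    coarseness = 1e6 if ps == 0 else 1.0 / ps
    if ngp <= 1:
        contrast = 0.0
    else:
        ii, jj = np.meshgrid(i[live], i[live], indexing="ij")
        pi, pj = np.meshgrid(p[live], p[live], indexing="ij")
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum()
            / (ngp * (ngp - 1))
            * s.sum()
            / n_total
        )
    ipi = i[live] * p[live]
    denom_busy = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = 0.0 if denom_busy == 0 else ps / denom_busy
    ii, jj = np.meshgrid(i[live], i[live], indexing="ij")
    pi, pj = np.meshgrid(p[live], p[live], indexing="ij")
    si, sj = np.meshgrid(s[live], s[live], indexing="ij")
    complexity = float(
        (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_total
    )
    s_sum = float(s.sum())
    strength = 0.0 if s_sum == 0 else float(((pi + pj) * (ii - jj) ** 2).sum() / s_sum)
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def texture_features(
    image: np.ndarray,
    mask: np.ndarray,
    config: DiscretizationConfig | None = None,
) -> tuple[dict[str, float], set[str]]:
    """All 75 texture features, prefixed by family; returns (values, flags)."""
    config = config or DiscretizationConfig()
    mask = np.asarray(mask) > 0
    if mask.sum() < 2:
        raise ValueError("texture features need a mask with >= 2 voxels")
    levels, n_levels, degenerate = discretize(image, mask, config)
    values: dict[str, float] = {}
    for prefix, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("gldm", gldm_features),
        ("ngtdm", ngtdm_features),
    ):
        for name, val in fn(levels, n_levels).items():
            values[f"{prefix}_{name}"] = val
    flags: set[str] = set()
    if degenerate:
        flags = {k for k in values}  # single gray level: all texture is conventional
    return values, flags
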