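"""Assembly of the 93-feature vector and voxel-wise local feature maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretize import DiscretizationConfig
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    texture_features,
)

__all__ = [
    "FEATURE_CLASSES",
    "all_feature_names",
    "FeatureVector",
    "extract_all",
    "compute_feature",
    "feature_map",
]

FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

_EXPECTED_COUNTS = {
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}
for _cls, _names in FEATURE_CLASSES.items():
    assert len(_names) == _EXPECTED_COUNTS[_cls], _cls


def all_feature_names() -> list[str]:
    """The 93 feature names, class-prefixed, in stable order."""
    return [f"{cls}_{name}" for cls, names in FEATURE_CLASSES.items() for name in names]


@dataclass
class FeatureVector:
    """One extraction result: 93 named values plus degeneracy flags."""

    values: dict[str, float]
    image_kind: str = ""
    voi_label: str = ""
    degenerate: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        expected = all_feature_names()
        if list(self.values.keys()) != expected:
            raise ValueError(
                f"feature vector must hold exactly the {len(expected)} known features"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()))


def extract_all(
    image: np.ndarray,
    mask: np.ndarray,
    config: DiscretizationConfig | None = None,
    voxel_volume: float = 1.0,
    image_kind: str = "",
    voi_label: str = "",
) -> FeatureVector:
    """Extract the full 93-feature profile from one image restricted to a VOI."""
    config = config or DiscretizationConfig()
    fo, fo_flags = first_order_features(image, mask, config, voxel_volume)
    tx, tx_flags = texture_features(image, mask, config)
    values = {f"firstorder_{k}": v for k, v in fo.items()}
    values.update(tx)
    ordered = {name: values[name] for name in all_feature_names()}
    flags = {f"firstorder_{k}" for k in fo_flags} | tx_flags
    return FeatureVector(ordered, image_kind, voi_label, flags)


def compute_feature(
    image: np.ndarray,
    mask: np.ndarray,
    feature_name: str,
    config: DiscretizationConfig | None = None,
    voxel_volume: float = 1.0,
) -> float:
    """Compute a single named feature (cheaper than a full extraction for maps)."""
    cls, _, short = feature_name.partition("_")
    if cls not in FEATURE_CLASSES or short not in FEATURE_CLASSES[cls]:
        raise KeyError(f"unknown feature {feature_name!r}")
    config = config or DiscretizationConfig()
    if cls == "firstorder":
        return first_order_features(image, mask, config, voxel_volume)[0][short]
    from .discretize import discretize
    from . import texture as _tx

    levels, n_levels, _ = discretize(image, mask, config)
    fn = {
        "glcm": _tx.glcm_features,
        "glrlm": _tx.glrlm_features,
        "glszm": _tx.glszm_features,
        "gldm": _tx.gldm_features,
        "ngtdm": _tx.ngtdm_features,
    }[cls]
    return fn(levels, n_levels)[short]


def feature_map(
    image: np.ndarray,
    mask: np.ndarray,
    feature_name: str,
    window_voxels: int = 5,
    config: DiscretizationConfig | None = None,
    fill_value: float = np.nan,
) -> np.ndarray:
    """Voxel-wise local feature map over a sliding cubic window.

    For every in-mask voxel the named feature is computed on the
    ``window_voxels``³ cube centred there (clipped at the image borders);
    voxels outside the mask are set to ``fill_value``. This is a
    visualization aid — cost grows linearly with the mask size.
    """
    if window_voxels < 3 or window_voxels % 2 == 0:
        raise ValueError("window_voxels must be odd and >= 3")
    cls, _, short = feature_name.partition("_")
    if cls not in FEATURE_CLASSES or short not in FEATURE_CLASSES[cls]:
        raise KeyError(f"unknown feature {feature_name!r}")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) > 0
    half = window_voxels // 2
    out = np.full(image.shape, fill_value, dtype=float)
    for x, y, z in np.argwhere(mask):
        sl = tuple(
            slice(max(c - half, 0), min(c + half + 1, n))
            for c, n in zip((x, y, z), image.shape)
        )
        cube = image[sl]
        out[x, y, z] = compute_feature(
            cube, np.ones(cube.shape, dtype=bool), feature_name, config
        )
    return out
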