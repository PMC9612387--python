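"""The long-format feature table shared by screening and classification.

One row per (patient, VOI, image kind) with identifier columns
``patient_id``, ``phenotype`` ("isometabolic" | "photopenic"), ``voi``
("tumor" | "mirrored"), ``kind`` (parametric image kind), followed by the 93
feature columns and a ``degenerate`` column listing flagged features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import all_feature_names
from .maps import IMAGE_KINDS

__all__ = ["ID_COLUMNS", "validate_feature_table", "subgroup_mask", "design_matrix"]

ID_COLUMNS = ("patient_id", "phenotype", "voi", "kind")
SUBGROUPS = ("all", "isometabolic", "photopenic")


def validate_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    missing += [c for c in all_feature_names() if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing[:5]}...")
    if table.duplicated(subset=["patient_id", "voi", "kind"]).any():
        raise ValueError("duplicated (patient, voi, kind) rows")
    counts = table.groupby(["patient_id", "kind"])["voi"].nunique()
    if (counts != 2).any():
        raise ValueError("every patient needs both tumor and mirrored rows per kind")


def subgroup_mask(table: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup not in SUBGROUPS:
        raise ValueError(f"subgroup must be one of {SUBGROUPS}")
    if subgroup == "all":
        return pd.Series(True, index=table.index)
    return table["phenotype"] == subgroup


def design_matrix(
    table: pd.DataFrame,
    feature_set: str | tuple[str, str],
    subgroup: str = "all",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Samples-are-VOIs design matrix for classification.

    ``feature_set`` is an image kind ("TBR_20_40", "TBR_5_15", "TTP"), "All"
    (all three kinds side by side), or a ``(kind, feature_name)`` singleton.

    Returns ``(X, y, groups, column_names)`` with one row per (patient, VOI),
    ``y`` = 1 for tumor rows and 0 for mirrored, ``groups`` = patient ids.
    """
    sub = table[subgroup_mask(table, subgroup)]
    feats = all_feature_names()
    if isinstance(feature_set, tuple):
        kinds, cols = [feature_set[0]], [feature_set[1]]
    elif feature_set == "All":
        kinds, cols = list(IMAGE_KINDS), feats
    elif feature_set in IMAGE_KINDS:
        kinds, cols = [feature_set], feats
    else:
        raise ValueError(f"unknown feature_set {feature_set!r}")

    wide = sub[sub["kind"].isin(kinds)].pivot(
        index=["patient_id", "voi"], columns="kind", values=cols
    )
    names = [f"{kind}:{feat}" for feat, kind in wide.columns]
    X = wide.to_numpy(dtype=float)
    idx = wide.index.to_frame(index=False)
    y = (idx["voi"] == "tumor").to_numpy(dtype=int)
    groups = idx["patient_id"].to_numpy()
    return X, y, groups, names
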