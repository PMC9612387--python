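"""Nested cross-validated logistic-regression discrimination of tumor VOIs.

Samples are VOIs (tumor = 1, mirrored background = 0; two rows per patient)
and outer folds are stratified on the class label only — deliberately
reproducing the acknowledged limitation of treating the paired VOIs as
independent samples. ``group_by_patient=True`` keeps the two VOIs of a
patient in the same fold (the corrected design; off by default).

Per outer training fold the full pipeline is refit from scratch:
standardize features (mean/unit variance), drop zero-variance features, tune
the inverse regularization strength C of a balanced L2 logistic regression by
inner stratified 5-fold CV on ROC-AUC, refit at the chosen C, then score the
held-out outer fold with the continuous decision function. Nothing computed
from outer-test rows ever enters the fit — the scaler, the retained columns
and C are all outer-train-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .maps import IMAGE_KINDS
from .tables import design_matrix, validate_feature_table

__all__ = [
    "ClassificationConfig",
    "CVReport",
    "nested_cv_auc",
    "univariate_auc",
    "leaky_best_feature_auc",
    "TumorClassifier",
    "CVResults",
]

FEATURE_SETS = ("TBR_20_40", "TBR_5_15", "TTP", "All")


@dataclass(frozen=True)
class ClassificationConfig:
    """Settings of the nested-CV logistic-regression procedure."""

    n_repeats: int = 50
    n_folds: int = 5
    inner_folds: int = 5
    C_grid: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))
    seed: int = 0
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_folds < 2 or self.inner_folds < 2:
            raise ValueError("need n_repeats >= 1 and folds >= 2")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid values must be > 0")


@dataclass
class CVReport:
    """Outer-fold AUCs for one feature set × subgroup."""

    feature_set: str
    subgroup: str
    fold_aucs: np.ndarray  # (n_repeats, n_folds)
    chosen_C: np.ndarray
    config: ClassificationConfig
    n_samples: int

    @property
    def mean(self) -> float:
        return float(self.fold_aucs.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_aucs.std(ddof=1))

    def summary(self) -> str:
        return (
            f"{self.feature_set} / {self.subgroup}: AUC {self.mean:.2f} ± {self.sd:.2f} "
            f"({self.config.n_repeats}×{self.config.n_folds} CV, n={self.n_samples})"
        )


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0  # zero-variance exclusion (constant after standardization)
    return mean, np.where(sd > 0, sd, 1.0), keep


def _fit_score(X_tr, y_tr, X_te, y_te, C: float, seed: int) -> float:
    # liblinear with default l2 penalty, balanced class weights
    clf = LogisticRegression(
        C=C, solver="liblinear", class_weight="balanced", random_state=seed
    )
    clf.fit(X_tr, y_tr)
    return float(roc_auc_score(y_te, clf.decision_function(X_te)))


def _tune_C(X, y, config: ClassificationConfig, seed: int) -> float:
    """Inner stratified CV over the C grid; ties go to the smaller C."""
    if len(config.C_grid) == 1:
        return float(config.C_grid[0])
    inner = StratifiedKFold(config.inner_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(config.C_grid))
    for tr, te in inner.split(X, y):
        if len(np.unique(y[te])) < 2:
            continue
        for ci, c in enumerate(config.C_grid):
            scores[ci] += _fit_score(X[tr], y[tr], X[te], y[te], c, seed)
    order = np.argsort(config.C_grid)
    best = order[int(np.argmax(scores[order]))]
    return float(config.C_grid[best])


def _rep_seed(master: int, rep: int, salt: int = 0) -> int:
    return int(
        np.random.SeedSequence(entropy=master, spawn_key=(salt, rep)).generate_state(1)[0]
        % (2**31)
    )


def nested_cv_auc(
    table: pd.DataFrame,
    feature_set: str | tuple[str, str],
    subgroup: str = "all",
    config: ClassificationConfig | None = None,
    permute_labels_seed: int | None = None,
) -> CVReport:
    """Repeated stratified nested-CV AUC for one feature set and subgroup.

    ``permute_labels_seed`` randomly permutes the class labels before CV —
    the null reference for calibration checks.
    """
    config = config or ClassificationConfig()
    validate_feature_table(table)
    X, y, groups, _ = design_matrix(table, feature_set, subgroup)
    if permute_labels_seed is not None:
        y = np.random.default_rng(permute_labels_seed).permutation(y)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < config.n_folds:
        raise ValueError("need at least n_folds samples per class")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")

    aucs = np.zeros((config.n_repeats, config.n_folds))
    chosen = np.zeros((config.n_repeats, config.n_folds))
    for rep in range(config.n_repeats):
        rs = _rep_seed(config.seed, rep)
        if config.group_by_patient:
            outer = StratifiedGroupKFold(config.n_folds, shuffle=True, random_state=rs)
            splits = outer.split(X, y, groups)
        else:
            outer = StratifiedKFold(config.n_folds, shuffle=True, random_state=rs)
            splits = outer.split(X, y)
        for k, (tr, te) in enumerate(splits):
            if len(np.unique(y[te])) < 2:
                raise ValueError("degenerate class distribution in an outer fold")
            mean, sd, keep = _standardize_fit(X[tr])
            if not keep.any():
                aucs[rep, k] = 0.5  # no informative feature survives
                chosen[rep, k] = np.nan
                continue
            Xtr = ((X[tr] - mean) / sd)[:, keep]
            Xte = ((X[te] - mean) / sd)[:, keep]
            c = _tune_C(Xtr, y[tr], config, _rep_seed(config.seed, rep, salt=1 + k))
            aucs[rep, k] = _fit_score(Xtr, y[tr], Xte, y[te], c, rs)
            chosen[rep, k] = c
    label = feature_set if isinstance(feature_set, str) else ":".join(feature_set)
    return CVReport(label, subgroup, aucs, chosen, config, n_samples=len(y))


def univariate_auc(
    table: pd.DataFrame,
    subgroup: str = "all",
    config: ClassificationConfig | None = None,
    image_kinds=IMAGE_KINDS,
) -> list[CVReport]:
    """Nested-CV AUC of every (image kind, feature) singleton, best first.

    Ties in mean AUC are broken by feature-set label so the ranking is
    deterministic.
    """
    from .features import all_feature_names

    config = config or ClassificationConfig()
    reports = [
        nested_cv_auc(table, (kind, feat), subgroup, config)
        for kind in image_kinds
        for feat in all_feature_names()
    ]
    return sorted(reports, key=lambda r: (-r.mean, r.feature_set))


def leaky_best_feature_auc(
    table: pd.DataFrame,
    subgroup: str = "all",
    config: ClassificationConfig | None = None,
) -> CVReport:
    """Negative control: select the best feature on the *full* data, then CV it.

    The selection step sees the test rows, so on null data this measurably
    inflates the AUC. Kept as an audit tool for leakage regression tests —
    never use it to report performance.
    """
    config = config or ClassificationConfig()
    X, y, _, names = design_matrix(table, "All", subgroup)
    full_aucs = [
        roc_auc_score(y, X[:, i]) if np.std(X[:, i]) > 0 else 0.5
        for i in range(X.shape[1])
    ]
    sym = [max(a, 1 - a) for a in full_aucs]
    kind, _, feat = names[int(np.argmax(sym))].partition(":")
    return nested_cv_auc(table, (kind, feat), subgroup, config)


class TumorClassifier:
    """Model object: tumor-vs-background discrimination from the feature table.

    ``fit()`` runs the nested-CV procedure for every requested feature set ×
    subgroup cell and returns a :class:`CVResults`.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        feature_sets=FEATURE_SETS,
        subgroups=("all", "isometabolic", "photopenic"),
        config: ClassificationConfig | None = None,
    ):
        validate_feature_table(table)
        self.table = table
        self.feature_sets = tuple(feature_sets)
        self.subgroups = tuple(subgroups)
        self.config = config or ClassificationConfig()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "TumorClassifier":
        return cls(table, **kwargs)

    def fit(self) -> "CVResults":
        reports = {
            (fs, sg): nested_cv_auc(self.table, fs, sg, self.config)
            for fs in self.feature_sets
            for sg in self.subgroups
        }
        return CVResults(self, reports)


@dataclass
class CVResults:
    """Fitted classification study: one CVReport per feature set × subgroup."""

    model: TumorClassifier
    reports: dict[tuple[str, str], CVReport]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_set": fs,
                    "subgroup": sg,
                    "auc_mean": r.mean,
                    "auc_sd": r.sd,
                    "n_samples": r.n_samples,
                }
                for (fs, sg), r in self.reports.items()
            ]
        )

    def summary(self) -> str:
        df = self.to_frame()
        mean = df.pivot(index="feature_set", columns="subgroup", values="auc_mean")
        sd = df.pivot(index="feature_set", columns="subgroup", values="auc_sd")
        cfg = self.model.config
        lines = [
            f"Nested-CV logistic regression AUC ({cfg.n_repeats}×{cfg.n_folds} "
            "stratified CV, balanced L2)",
            "",
        ]
        cols = [c for c in ("all", "isometabolic", "photopenic") if c in mean.columns]
        lines.append(f"{'features':<12}" + "".join(f"{c:>22}" for c in cols))
        for fs in [f for f in FEATURE_SETS if f in mean.index]:
            cells = "".join(
                f"{mean.loc[fs, c]:>14.2f} ± {sd.loc[fs, c]:.2f}" for c in cols
            )
            lines.append(f"{fs:<12}" + cells)
        return "\n".join(lines)
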