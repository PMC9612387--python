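"""Paired tumor-vs-background feature screening.

For each of the 93 features and each parametric image kind, the tumor value
is compared against the mirrored-background value of the same patient with a
two-sided Wilcoxon signed-rank test. Zero differences are dropped (the
classic convention). For n <= 25 usable pairs the p-value comes from the
exact permutation distribution of the signed midrank sum (a shift DP, valid
with tied |differences|); beyond that a normal approximation with tie and
continuity corrections is used.

The census arranges the count and percentage of significant features
(p < alpha, strict) as an image-kind × cohort-subgroup grid. No
multiple-testing correction is applied to the primary census; a
Benjamini–Hochberg-adjusted count is reported as a separate, clearly
supplementary column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import all_feature_names
from .maps import IMAGE_KINDS
from .tables import SUBGROUPS, subgroup_mask, validate_feature_table

__all__ = [
    "WilcoxonResult",
    "signed_rank_test",
    "paired_wilcoxon",
    "significance_census",
    "PairedFeatureScreen",
    "ScreenResults",
]


@dataclass(frozen=True)
class WilcoxonResult:
    feature: str
    image_kind: str
    n_pairs: int
    statistic: float
    p_value: float
    direction: int  # sign of the median paired difference (tumor - background)
    degenerate: bool = False


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact permutation p over all sign assignments of the (mid)ranks."""
    r2 = np.rint(2.0 * ranks).astype(np.int64)  # doubled ranks are integers
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    n_assign = 2.0 ** len(r2)
    w2 = int(np.rint(2.0 * w_plus))
    p_ge = dist[w2:].sum() / n_assign
    p_le = dist[: w2 + 1].sum() / n_assign
    return min(1.0, 2.0 * min(p_ge, p_le))


def signed_rank_test(differences, exact_max_n: int = 25) -> tuple[float, float, int, bool]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(W_plus, p_value, n_used, degenerate)``. Zero differences are
    dropped; if every difference is zero the test is degenerate and the
    p-value is NaN.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return np.nan, np.nan, 0, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _exact_two_sided_p(ranks, w_plus), n, False
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return w_plus, np.nan, n, True
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(abs(z))), n, False


def paired_wilcoxon(
    table: pd.DataFrame,
    image_kind: str,
    subgroup: str = "all",
    min_pairs: int = 5,
) -> list[WilcoxonResult]:
    """Per-feature paired tests of tumor vs. mirrored VOIs for one image kind."""
    validate_feature_table(table)
    sub = table[subgroup_mask(table, subgroup) & (table["kind"] == image_kind)]
    tumor = sub[sub["voi"] == "tumor"].set_index("patient_id").sort_index()
    mirr = sub[sub["voi"] == "mirrored"].set_index("patient_id").sort_index()
    common = tumor.index.intersection(mirr.index)
    if len(common) < min_pairs:
        raise ValueError(
            f"only {len(common)} complete pairs for {image_kind}/{subgroup}; need {min_pairs}"
        )
    results = []
    for feat in all_feature_names():
        diffs = (tumor.loc[common, feat] - mirr.loc[common, feat]).to_numpy(dtype=float)
        w, p, n_used, degenerate = signed_rank_test(diffs)
        results.append(
            WilcoxonResult(
                feature=feat,
                image_kind=image_kind,
                n_pairs=len(common),
                statistic=w,
                p_value=p,
                direction=int(np.sign(np.median(diffs))),
                degenerate=degenerate,
            )
        )
    return results


def significance_census(
    results_by_cell: dict[tuple[str, str], list[WilcoxonResult]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count features with p < alpha per (image kind, subgroup) cell.

    Returns a tidy frame with the count, the percentage of the 93 features
    (rounded to whole percent), and a supplementary Benjamini–Hochberg count.
    """
    rows = []
    for (kind, subgroup), results in results_by_cell.items():
        p = np.array([r.p_value for r in results])
        valid = np.isfinite(p)
        n_feat = len(results)
        n_sig = int((p[valid] < alpha).sum())
        bh = stats.false_discovery_control(p[valid]) if valid.any() else np.array([])
        rows.append(
            {
                "kind": kind,
                "subgroup": subgroup,
                "n_features": n_feat,
                "n_significant": n_sig,
                "pct_significant": round(100.0 * n_sig / n_feat),
                "n_significant_bh": int((bh < alpha).sum()),
            }
        )
    return pd.DataFrame(rows)


class PairedFeatureScreen:
    """Model object for the tumor-vs-background feature screen.

    Parameters
    ----------
    table : DataFrame
        Long-format feature table (see :mod:`fetrad.tables`).
    image_kinds, subgroups : sequences, optional
        Which cells of the kind × subgroup grid to test (defaults: all).
    """

    def __init__(self, table, image_kinds=IMAGE_KINDS, subgroups=SUBGROUPS, alpha=0.05):
        validate_feature_table(table)
        self.table = table
        self.image_kinds = tuple(image_kinds)
        self.subgroups = tuple(subgroups)
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "PairedFeatureScreen":
        return cls(table, **kwargs)

    def fit(self) -> "ScreenResults":
        cells = {}
        for kind in self.image_kinds:
            for sg in self.subgroups:
                cells[(kind, sg)] = paired_wilcoxon(self.table, kind, sg)
        return ScreenResults(self, cells)


@dataclass
class ScreenResults:
    """Fitted screen: per-feature test results and the significance census."""

    model: PairedFeatureScreen
    cells: dict[tuple[str, str], list[WilcoxonResult]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": kind,
                "subgroup": sg,
                "feature": r.feature,
                "n_pairs": r.n_pairs,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
                "degenerate": r.degenerate,
            }
            for (kind, sg), results in self.cells.items()
            for r in results
        ]
        return pd.DataFrame(rows)

    def census(self, alpha: float | None = None) -> pd.DataFrame:
        return significance_census(self.cells, alpha or self.model.alpha)

    def summary(self) -> str:
        census = self.census()
        grid = census.pivot(index="kind", columns="subgroup", values="n_significant")
        pct = census.pivot(index="kind", columns="subgroup", values="pct_significant")
        lines = [
            "Paired Wilcoxon screen: significant features of 93 (p < "
            f"{self.model.alpha:g})",
            "",
        ]
        cols = [c for c in ("all", "isometabolic", "photopenic") if c in grid.columns]
        header = f"{'image':<12}" + "".join(f"{c:>20}" for c in cols)
        lines.append(header)
        for kind in grid.index:
            cells = "".join(
                f"{grid.loc[kind, c]:>14d} ({pct.loc[kind, c]:>3.0f}%)" for c in cols
            )
            lines.append(f"{kind:<12}" + cells)
        return "\n".join(lines)
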