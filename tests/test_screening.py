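import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import make_feature_table
from fetrad.screening import (
    PairedFeatureScreen,
    WilcoxonResult,
    paired_wilcoxon,
    signed_rank_test,
    significance_census,
)


def _enumerated_two_sided_p(diffs):
    """Independent oracle: enumerate all 2^n sign assignments of the ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    return min(1.0, 2 * min(p_ge, p_le))


class TestSignedRank:
    def test_all_positive_unit_differences_exact_p(self):
        """n=10 identical +1 differences: two-sided exact p = 2/1024."""
        w, p, n, degenerate = signed_rank_test(np.ones(10))
        assert not degenerate and n == 10
        assert p == pytest.approx(2 / 1024)
        assert p == pytest.approx(_enumerated_two_sided_p(np.ones(10)))

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=9)
        d = np.where(d == 0, 0.1, d)
        _, p, _, _ = signed_rank_test(d)
        assert p == pytest.approx(_enumerated_two_sided_p(d))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 1.0, size=12)
        _, p, _, _ = signed_rank_test(d)
        p_scipy = stats.wilcoxon(d, method="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(p_scipy)

    def test_approx_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.2, 1.0, size=40)
        _, p, _, _ = signed_rank_test(d)
        p_scipy = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert p == pytest.approx(p_scipy, rel=1e-6)

    def test_all_zero_differences_degenerate(self):
        _, p, n, degenerate = signed_rank_test(np.zeros(8))
        assert degenerate and n == 0 and np.isnan(p)

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5, 3.0, 1.5, -1.0, 0.7, 2.2])
        _, p1, n1, _ = signed_rank_test(d)
        _, p2, n2, _ = signed_rank_test(d[d != 0])
        assert n1 == n2 == 8 and p1 == p2


class TestPairedWilcoxon:
    def test_row_permutation_invariance(self):
        table = make_feature_table(n_patients=8)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = paired_wilcoxon(table, "TTP")
        b = paired_wilcoxon(shuffled, "TTP")
        assert [r.p_value for r in a] == [r.p_value for r in b]

    def test_label_swap_keeps_p_flips_direction(self):
        table = make_feature_table(
            n_patients=8, effect={("TTP", "firstorder_Mean"): 3.0}
        )
        swapped = table.copy()
        swapped["voi"] = swapped["voi"].map({"tumor": "mirrored", "mirrored": "tumor"})
        a = {r.feature: r for r in paired_wilcoxon(table, "TTP")}
        b = {r.feature: r for r in paired_wilcoxon(swapped, "TTP")}
        for feat in a:
            assert a[feat].p_value == pytest.approx(b[feat].p_value, nan_ok=True)
            assert a[feat].direction == -b[feat].direction

    def test_insufficient_pairs_rejected(self):
        table = make_feature_table(n_patients=3)
        with pytest.raises(ValueError, match="pairs"):
            paired_wilcoxon(table, "TTP")

    def test_detects_injected_effect(self):
        table = make_feature_table(
            n_patients=12, effect={("TTP", "firstorder_Mean"): 5.0}
        )
        results = {r.feature: r for r in paired_wilcoxon(table, "TTP")}
        r = results["firstorder_Mean"]
        assert r.p_value < 0.01 and r.direction > 0


class TestCensus:
    def _fake_results(self, pvals, kind="TTP"):
        return [
            WilcoxonResult(f"f{i}", kind, 10, 1.0, p, 1) for i, p in enumerate(pvals)
        ]

    def test_all_null_counts_zero(self):
        cells = {("TTP", "all"): self._fake_results([1.0] * 93)}
        census = significance_census(cells)
        assert census.loc[0, "n_significant"] == 0
        assert census.loc[0, "pct_significant"] == 0

    def test_64_of_93_rounds_to_69_percent(self):
        pvals = [0.01] * 64 + [0.5] * 29
        census = significance_census({("TTP", "all"): self._fake_results(pvals)})
        assert census.loc[0, "n_significant"] == 64
        assert census.loc[0, "pct_significant"] == 69

    def test_boundary_p_not_counted(self):
        """p == alpha is not significant (strict <)."""
        pvals = [0.05] * 93
        census = significance_census({("TTP", "all"): self._fake_results(pvals)})
        assert census.loc[0, "n_significant"] == 0


class TestScreenModel:
    def test_model_results_roundtrip(self):
        table = make_feature_table(n_patients=8)
        res = PairedFeatureScreen(table, subgroups=("all",)).fit()
        frame = res.to_frame()
        assert len(frame) == 3 * 93
        census = res.census()
        assert set(census["kind"]) == {"TBR_5_15", "TBR_20_40", "TTP"}
        assert "Paired Wilcoxon screen" in res.summary()

    def test_null_calibration_per_feature(self):
        """With no tumor effect, ~5% of features reach p < 0.05."""
        rates = []
        for seed in range(8):
            table = make_feature_table(n_patients=12, rng=np.random.default_rng(seed))
            results = paired_wilcoxon(table, "TBR_20_40")
            p = np.array([r.p_value for r in results])
            rates.append(np.mean(p < 0.05))
        assert 0.0 <= np.mean(rates) < 0.12  # 5% nominal, Monte-Carlo slack
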