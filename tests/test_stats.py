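"""Intactness filter, ROUT outlier screen, aggregation and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxmap import stats


def _cells(oxd, **cols):
    n = len(oxd)
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "slice_id": cols.pop("slice_id", ["s0"] * n),
        "region": cols.pop("region", ["CA1"] * n),
        "genotype": cols.pop("genotype", ["WT"] * n),
        "age_group": cols.pop("age_group", ["p50"] * n),
        "ratio": [0.5] * n,
        "oxd": oxd,
        "mecp2_positive": [None] * n,
        "included": [True] * n,
        "exclusion_reason": [None] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestFilterIntact:
    def test_range_rule(self):
        out = stats.filter_intact(_cells([0.03, 0.50, 0.96]))
        assert list(out["included"]) == [False, True, False]
        assert list(out.loc[~out["included"], "exclusion_reason"]) == ["range", "range"]

    def test_boundaries_kept_closed_interval(self):
        out = stats.filter_intact(_cells([0.05, 0.95]))
        assert out["included"].all()

    def test_undefined_oxd_excluded_with_reason(self):
        out = stats.filter_intact(_cells([np.nan, 0.5]))
        assert list(out["included"]) == [False, True]
        assert out["exclusion_reason"].iloc[0] == "undefined_oxd"

    def test_empty_input(self):
        out = stats.filter_intact(_cells([]))
        assert len(out) == 0

    def test_idempotent(self):
        once = stats.filter_intact(_cells([0.03, 0.5, 0.96]))
        twice = stats.filter_intact(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRout:
    def test_flags_gross_outlier_only(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95, 50.0]
        kept, flagged = stats.rout_outliers(vals, q=0.01)
        assert list(flagged) == [False, False, False, False, False, True]
        assert kept.sum() == 5

    def test_identical_values_unflagged(self):
        _, flagged = stats.rout_outliers([2.0] * 10, q=0.01)
        assert not flagged.any()

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            stats.rout_outliers([1.0, 2.0], q=0.01)

    @pytest.mark.parametrize("n", [20, 100, 1000])
    def test_false_flag_rate_on_clean_normal(self, n):
        """FDR control: at Q = 1 % the mean flagged fraction on clean
        Gaussian columns stays at or below ~2 %."""
        rng = np.random.default_rng(123)
        fracs = []
        for _ in range(60):
            _, flagged = stats.rout_outliers(rng.normal(0.5, 0.1, n), q=0.01)
            fracs.append(flagged.mean())
        assert np.mean(fracs) <= 0.02

    def test_planted_outliers_in_large_clean_column(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0.5, 0.05, 200), [5.0, -3.0]])
        _, flagged = stats.rout_outliers(vals, q=0.01)
        assert flagged[-2:].all()

    def test_apply_rout_per_group(self):
        df = pd.concat(
            [
                _cells([0.5, 0.51, 0.49, 0.5, 0.52, 0.94], region=["CA1"] * 6),
                _cells([0.7, 0.71, 0.69, 0.7, 0.72, 0.68], region=["DG"] * 6),
            ],
            ignore_index=True,
        )
        out = stats.apply_rout(df, q=0.01)
        flagged = out[out["exclusion_reason"] == "rout_outlier"]
        assert len(flagged) == 1
        assert flagged["region"].iloc[0] == "CA1"
        assert flagged["oxd"].iloc[0] == 0.94


class TestAggregate:
    def test_slice_level_arithmetic(self):
        df = _cells(
            [0.6, 0.6, 0.8, 0.8],
            slice_id=["s0", "s0", "s1", "s1"],
        )
        out = stats.aggregate(df, level="slice")
        assert out["mean"].iloc[0] == pytest.approx(0.7)
        assert out["n"].iloc[0] == 2

    def test_single_slice_sd_undefined(self):
        out = stats.aggregate(_cells([0.6, 0.7]), level="slice")
        assert out["n"].iloc[0] == 1
        assert np.isnan(out["sd"].iloc[0])

    def test_slice_first_order_matters(self):
        """Unequal slice sizes: the slice-level mean weights slices
        equally, the cell-level mean weights cells equally."""
        df = _cells(
            [0.2] * 9 + [0.8],
            slice_id=["s0"] * 9 + ["s1"],
        )
        cell = stats.aggregate(df, level="cell")["mean"].iloc[0]
        slice_ = stats.aggregate(df, level="slice")["mean"].iloc[0]
        assert cell == pytest.approx(0.26)
        assert slice_ == pytest.approx(0.5)
        assert cell != slice_

    def test_only_included_cells_enter(self):
        df = _cells([0.5, 0.9])
        df.loc[1, "included"] = False
        out = stats.aggregate(df, level="cell")
        assert out["n"].iloc[0] == 1
        assert out["mean"].iloc[0] == pytest.approx(0.5)


class TestHolmSidak:
    def test_worked_example(self):
        adj = stats.holm_sidak_adjust([0.01, 0.03, 0.04])
        assert adj[0] == pytest.approx(0.029701, abs=1e-6)
        assert adj[1] == pytest.approx(0.0591, abs=1e-4)
        assert adj[2] == pytest.approx(0.0591, abs=1e-4)

    def test_matches_statsmodels(self):
        """Independent oracle: statsmodels' holm-sidak correction."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 12)
        _, expected, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(stats.holm_sidak_adjust(p), expected)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_dominance_and_monotonicity(self, pvals):
        adj = stats.holm_sidak_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)


class TestWelch:
    def test_identical_groups(self):
        res = stats.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [0.0, 0.0, 0.0, 1.0], [1.0, 1.0, 1.0, 0.0]
        assert stats.welch_t(a, b).t == pytest.approx(-stats.welch_t(b, a).t)

    def test_matches_scipy_df(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 12)
        res = stats.welch_t(a, b)
        from scipy.stats import ttest_ind

        ref = ttest_ind(a, b, equal_var=False)
        assert res.p == pytest.approx(ref.pvalue)

    def test_degenerate_variance_named(self):
        with pytest.raises(ValueError, match="group b"):
            stats.welch_t([1.0, 2.0], [3.0, 3.0])


class TestTwoWayAnova:
    def _design(self, rng, effect_geno=0.0, effect_age=0.0, n=12):
        rows = []
        for g in ("WT", "Mecp2+/-"):
            for a in ("p50", "gt_p100"):
                mu = 0.5
                if g != "WT":
                    mu += effect_geno
                if a != "p50":
                    mu += effect_age
                for v in rng.normal(mu, 0.08, n):
                    rows.append({"genotype": g, "age_group": a, "oxd": v})
        return pd.DataFrame(rows)

    def test_detects_planted_genotype_effect(self):
        rng = np.random.default_rng(0)
        res = stats.two_way_anova_holm_sidak(self._design(rng, effect_geno=0.2))
        assert res.anova is not None
        pure_geno = res.pairwise[res.pairwise["symbol"] == "#"]
        assert (pure_geno["p_adj"] < 0.01).all()
        assert set(pure_geno["marker"]) == {"##"}

    def test_identical_groups_p_one(self):
        df = pd.DataFrame(
            {
                "genotype": ["WT"] * 4 + ["Mecp2+/-"] * 4,
                "age_group": ["p50", "p50", "gt_p100", "gt_p100"] * 2,
                "oxd": [0.4, 0.6, 0.4, 0.6, 0.4, 0.6, 0.4, 0.6],
            }
        )
        res = stats.two_way_anova_holm_sidak(df)
        # every contrast between identical data has t = 0, raw p = 1
        assert np.allclose(res.pairwise["p_raw"], 1.0)

    def test_six_contrasts_for_full_design(self):
        rng = np.random.default_rng(1)
        res = stats.two_way_anova_holm_sidak(self._design(rng))
        assert len(res.pairwise) == 6
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()

    def test_empty_design_cell_reports_no_anova(self):
        rng = np.random.default_rng(2)
        df = self._design(rng)
        df = df[~((df["genotype"] == "WT") & (df["age_group"] == "p50"))]
        res = stats.two_way_anova_holm_sidak(df)
        assert res.anova is None
        assert len(res.pairwise) == 3  # contrasts among remaining cells

    def test_null_familywise_marker_rate(self):
        """Under a no-effect generator the fraction of simulations with
        any significant marker stays near the nominal familywise level."""
        rng = np.random.default_rng(42)
        hits = 0
        n_sim = 150
        for _ in range(n_sim):
            res = stats.two_way_anova_holm_sidak(self._design(rng, n=8))
            hits += int((res.pairwise["p_adj"] < 0.05).any())
        rate = hits / n_sim
        assert 0.005 <= rate <= 0.12


def test_significance_markers():
    assert stats.significance_marker(0.2) == ""
    assert stats.significance_marker(0.03) == "*"
    assert stats.significance_marker(0.004) == "**"
    assert stats.significance_marker(0.004, "#") == "##"
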