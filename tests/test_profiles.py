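"""Group summaries, filtering, PCA, t-tests, ΔΔCt, regional stats, switch."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoswitch.profiles import (
    DEFAULT_CPM_CUTOFF,
    benjamini_hochberg,
    ddct,
    filter_mean_expression,
    fit_late_plateau,
    group_summary,
    log_ttest,
    pca_explained_variance,
    regional_comparison,
    switch_report,
)


class TestGroupSummary:
    MATRIX = pd.DataFrame(
        {"s1": [4.0, 1.0], "s2": [6.0, 1.0], "s3": [9.0, 2.0]},
        index=["fA", "fB"],
    )

    def test_hand_computed_mean_and_sd(self):
        out = group_summary(self.MATRIX, {"s1": "g1", "s2": "g1", "s3": "g2"})
        assert out.loc[("fA", "g1"), "mean"] == 5.0
        assert out.loc[("fA", "g1"), "sd"] == pytest.approx(np.sqrt(2))
        assert out.loc[("fA", "g1"), "n"] == 2

    def test_equal_replicates_have_zero_sd(self):
        out = group_summary(self.MATRIX, {"s1": "g", "s2": "g"})
        assert out.loc[("fB", "g"), "sd"] == 0.0

    def test_single_sample_group_flagged(self):
        out = group_summary(self.MATRIX, {"s3": "solo"})
        assert out.loc[("fA", "solo"), "mean"] == 9.0
        assert out.loc[("fA", "solo"), "sd"] == 0.0
        assert not out.loc[("fA", "solo"), "sd_defined"]

    def test_sample_order_invariance(self):
        d1 = {"s1": "g", "s2": "g", "s3": "h"}
        d2 = dict(reversed(list(d1.items())))
        pd.testing.assert_frame_equal(
            group_summary(self.MATRIX, d1).sort_index(),
            group_summary(self.MATRIX, d2).sort_index(),
        )

    def test_unknown_sample_errors(self):
        with pytest.raises(KeyError):
            group_summary(self.MATRIX, {"nope": "g"})


class TestFilterMeanExpression:
    def test_boundary_is_inclusive(self):
        m = pd.DataFrame({"s1": [10.0], "s2": [10.0]}, index=["f"])
        assert len(filter_mean_expression(m, 10.0)) == 1

    def test_all_zero_feature_removed(self):
        m = pd.DataFrame({"s1": [0.0, 5.0], "s2": [0.0, 25.0]}, index=["z", "k"])
        assert list(filter_mean_expression(m, DEFAULT_CPM_CUTOFF).index) == ["k"]

    def test_means_straddling_cutoff(self):
        m = pd.DataFrame(
            {
                "s1": [9.8, 10.2],
                "s2": [10.0, 10.0],
                "s3": [9.9, 10.1],
                "s4": [9.9, 10.1],
            },
            index=["below", "above"],
        )  # grand means 9.9 and 10.1
        kept = filter_mean_expression(m, 10.0)
        assert list(kept.index) == ["above"]


class TestPca:
    def test_rank_one_data_loads_on_first_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame(np.outer([1.0, 2.0, 0.5], base), columns=list("abcd"))
        res = pca_explained_variance(m, log=False)
        assert res.explained_variance_fractions[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_descending(self, rng):
        m = pd.DataFrame(rng.random((10, 6)))
        res = pca_explained_variance(m, log=False)
        f = res.explained_variance_fractions
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(f) <= 1e-12).all()

    def test_two_by_two_covariance_fixture_vs_hand_eigendecomposition(self):
        """Features with sample covariance diag(2, 1): fractions (2/3, 1/3)."""
        f1 = np.array([np.sqrt(2), -np.sqrt(2), 0.0])
        f2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(3)
        m = pd.DataFrame([f1, f2], index=["f1", "f2"], columns=["s1", "s2", "s3"])
        cov = np.cov(m.to_numpy())
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        hand = eigvals / eigvals.sum()
        assert hand == pytest.approx([2 / 3, 1 / 3])
        res = pca_explained_variance(m, log=False)
        assert res.explained_variance_fractions == pytest.approx(hand, abs=1e-9)

    def test_feature_reordering_invariance(self, rng):
        m = pd.DataFrame(rng.random((8, 5)), index=[f"f{i}" for i in range(8)])
        shuffled = m.sample(frac=1, random_state=1)
        a = pca_explained_variance(m, log=False).explained_variance_fractions
        b = pca_explained_variance(shuffled, log=False).explained_variance_fractions
        assert a == pytest.approx(b, abs=1e-9)

    def test_duplicating_a_high_variance_feature_raises_pc1(self, rng):
        m = pd.DataFrame(rng.random((6, 8)))
        m.iloc[0] *= 20  # dominant feature
        dup = pd.concat([m, m.iloc[[0]]], ignore_index=True)
        a = pca_explained_variance(m, log=False).explained_variance_fractions[0]
        b = pca_explained_variance(dup, log=False).explained_variance_fractions[0]
        assert b > a

    def test_constant_matrix_is_an_error(self):
        m = pd.DataFrame(np.ones((4, 5)))
        with pytest.raises(ValueError):
            pca_explained_variance(m, log=False)


class TestLogTtest:
    def test_identical_groups(self):
        res = log_ttest([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
        r1, r2 = log_ttest(a, b), log_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_reference_on_example(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = log_ttest(a, b, already_log=True)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_reference_on_random_cases(self, rng):
        """Student and Welch forms against scipy on 100 random small groups."""
        for _ in range(100):
            na, nb = rng.integers(2, 8, 2)
            a = rng.gamma(2.0, 50.0, na)
            b = rng.gamma(2.0, 80.0, nb)
            la, lb = np.log2(a + 1), np.log2(b + 1)
            for welch in (False, True):
                res = log_ttest(a, b, welch=welch)
                ref = stats.ttest_ind(la, lb, equal_var=not welch)
                assert res.t == pytest.approx(ref.statistic, abs=1e-9)
                assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_unequal_constant_groups_error(self):
        with pytest.raises(ValueError):
            log_ttest([1.0, 1.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            log_ttest([1.0], [2.0, 3.0])

    def test_benjamini_hochberg_monotone(self):
        p = [0.001, 0.01, 0.04, 0.2, 0.9]
        adj = benjamini_hochberg(p)
        assert (adj >= np.array(p)).all()


PLATE = pd.DataFrame(
    [
        ("s1", "cal", "Tgt", 20.0),
        ("s2", "test", "Tgt", 22.0),
        ("s1", "cal", "Ref", 18.0),
        ("s2", "test", "Ref", 18.0),
    ],
    columns=["sample", "group", "gene", "Ct"],
)


class TestDdct:
    def test_hand_computed_example(self):
        res = ddct(PLATE, ["Tgt"], "Ref", "cal").set_index("sample")
        assert res.loc["s2", "ddct"] == pytest.approx(2.0, abs=1e-12)
        assert res.loc["s2", "rel_expr"] == pytest.approx(0.25, abs=1e-12)

    def test_calibrator_relative_expression_is_one(self):
        res = ddct(PLATE, ["Tgt"], "Ref", "cal").set_index("sample")
        assert res.loc["s1", "rel_expr"] == pytest.approx(1.0, abs=1e-12)

    def test_calibrator_group_mean_dct_maps_to_unity(self, rng):
        plate = []
        for i in range(4):
            grp = "cal" if i < 2 else "test"
            plate.append((f"s{i}", grp, "T", 20 + rng.normal()))
            plate.append((f"s{i}", grp, "R", 17 + rng.normal()))
        plate = pd.DataFrame(plate, columns=["sample", "group", "gene", "Ct"])
        res = ddct(plate, ["T"], "R", "cal")
        cal_mean_ddct = res[res["group"] == "cal"]["ddct"].mean()
        assert 2.0 ** (-cal_mean_ddct) == pytest.approx(1.0, abs=1e-12)

    def test_lowering_target_ct_by_one_doubles_expression(self):
        plate = PLATE.copy()
        plate.loc[(plate["sample"] == "s2") & (plate["gene"] == "Tgt"), "Ct"] = 21.0
        res = ddct(plate, ["Tgt"], "Ref", "cal").set_index("sample")
        assert res.loc["s2", "rel_expr"] == pytest.approx(0.5, abs=1e-12)

    def test_missing_reference_names_sample(self):
        broken = PLATE[~((PLATE["sample"] == "s2") & (PLATE["gene"] == "Ref"))]
        with pytest.raises(ValueError, match="s2"):
            ddct(broken, ["Tgt"], "Ref", "cal")

    def test_nonpositive_ct_rejected(self):
        bad = PLATE.copy()
        bad.loc[0, "Ct"] = -1.0
        with pytest.raises(ValueError):
            ddct(bad, ["Tgt"], "Ref", "cal")


class TestRegionalComparison:
    @staticmethod
    def _matrix(rng, fold):
        sup = 100.0 * np.ones(4) * rng.lognormal(0, 0.05, 4)
        inf = (100.0 / fold) * np.ones(4) * rng.lognormal(0, 0.05, 4)
        m = pd.DataFrame(
            {
                **{f"sup{i}": [sup[i], inf[i]] for i in range(4)},
                **{f"inf{i}": [inf[i], sup[i]] for i in range(4)},
            },
            index=["Opn1mw_like", "Opn1sw_like"],
        )
        regions = {f"sup{i}": "superior" for i in range(4)}
        regions.update({f"inf{i}": "inferior" for i in range(4)})
        return m, regions

    def test_counter_gradient_genes_have_opposite_t_signs(self, rng):
        m, regions = self._matrix(rng, fold=4.0)
        res = regional_comparison(m, regions, ["Opn1mw_like", "Opn1sw_like"])
        assert res.loc["Opn1mw_like", "t"] * res.loc["Opn1sw_like", "t"] < 0

    def test_identical_regions_give_fold_one_p_one(self):
        m = pd.DataFrame(
            {"a": [5.0], "b": [5.0], "c": [5.0], "d": [5.0]}, index=["g"]
        )
        regions = {"a": "superior", "b": "superior", "c": "inferior", "d": "inferior"}
        res = regional_comparison(m, regions, ["g"])
        assert res.loc["g", "fold"] == 1.0
        assert res.loc["g", "p"] == 1.0

    def test_known_fourfold_difference_recovered(self, rng):
        m, regions = self._matrix(rng, fold=4.0)
        res = regional_comparison(m, regions, ["Opn1mw_like"])
        assert 3.5 <= res.loc["Opn1mw_like", "fold"] <= 4.5
        assert res.loc["Opn1mw_like", "p"] < 0.05

    def test_absent_region_errors(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            regional_comparison(m, {"a": "superior", "b": "superior"}, ["g"])


def _ages(ts):
    return pd.DataFrame(
        {"age_label": [f"A{t}" for t in ts], "age_t": ts},
        index=[f"A{t}" for t in ts],
    )


class TestSwitchReport:
    def test_crossing_is_first_strict_exceedance(self):
        ages = _ages([0.0, 5.0, 10.0, 15.0])
        iso1 = pd.Series([1.0, 4.0, 9.0, 9.0], index=ages.index)
        iso2 = pd.Series([9.0, 4.0, 1.0, 0.5], index=ages.index)
        whole = iso1 + iso2
        rep = switch_report(ages, iso1, iso2, whole)
        assert rep.crossing_age_label == "A10.0"

    def test_identical_trajectories_have_no_crossing(self):
        ages = _ages([0.0, 5.0, 10.0])
        v = pd.Series([1.0, 2.0, 3.0], index=ages.index)
        rep = switch_report(ages, v, v, 2 * v)
        assert rep.crossing_age_label is None

    def test_single_isoform_dataset_flagged_degenerate(self):
        ages = _ages([0.0, 5.0, 10.0])
        iso1 = pd.Series([1.0, 5.0, 9.0], index=ages.index)
        flat = pd.Series([0.0, 0.0, 0.0], index=ages.index)
        rep = switch_report(ages, iso1, flat, iso1, iso1, flat)
        assert rep.degenerate and rep.masked is None

    def test_masking_diagnostic_on_clean_switch(self):
        ages = _ages([-5.0, 0.0, 5.0, 10.0, 20.0, 30.0])
        t = ages["age_t"].to_numpy()
        true1 = pd.Series(60 / (1 + np.exp(-(t - 8) / 3)), index=ages.index)
        true2 = pd.Series(100 * np.exp(-((t + 5) ** 2) / 72), index=ages.index)
        whole = true1 + true2
        rep = switch_report(ages, true1, true2, whole, true1, true2)
        assert rep.recovery_iso1 == pytest.approx(1.0)
        assert rep.recovery_iso2 == pytest.approx(1.0)
        assert rep.masked is True

    def test_too_few_ages_rejected(self):
        ages = _ages([0.0, 1.0])
        v = pd.Series([1.0, 2.0], index=ages.index)
        with pytest.raises(ValueError):
            switch_report(ages, v, v, v)


class TestFitLatePlateau:
    def test_recovers_midpoint_from_clean_curve(self):
        t = np.array([-5, -2, 1, 3, 5, 7, 9, 11, 21, 30, 60.0])
        y = 60 / (1 + np.exp(-(t - 8) / 3))
        A, t50, s = fit_late_plateau(t, y)
        assert t50 == pytest.approx(8.0, abs=1e-6)
        assert A == pytest.approx(60.0, rel=1e-6)
        assert s == pytest.approx(3.0, abs=1e-6)
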