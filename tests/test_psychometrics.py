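"""ROC/AUC, DeLong, Youden, ICC, Pearson and ANCOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from icf_adl import (
    DegenerateComparisonError,
    OneClassError,
    auc,
    delong_compare,
    evans_strength,
    group_compare,
    icc_two_way,
    pearson_ci,
    validity_report,
    youden_cutoff,
)


def pair_count_auc(pos, neg):
    """Exhaustive concordant-pair AUC: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        r = auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.ci_high == 1.0  # clipped

    def test_label_flip_symmetry(self):
        scores = [3, 1, 4, 1, 5, 9, 2, 6]
        labels = [0, 1, 0, 0, 1, 1, 0, 1]
        flipped = [1 - y for y in labels]
        assert auc(scores, labels).auc == pytest.approx(
            1 - auc(scores, flipped).auc)

    @given(st.lists(st.integers(0, 6), min_size=5, max_size=5),
           st.lists(st.integers(0, 6), min_size=5, max_size=5))
    def test_equals_exhaustive_pair_counting(self, pos, neg):
        scores = neg + pos
        labels = [0] * 5 + [1] * 5
        assert auc(scores, labels).auc == pytest.approx(pair_count_auc(pos, neg))

    def test_one_class_rejected(self):
        with pytest.raises(OneClassError):
            auc([1, 2, 3], [1, 1, 1])

    def test_constant_scores_warn_half(self):
        with pytest.warns(UserWarning, match="constant"):
            r = auc([2, 2, 2, 2], [0, 0, 1, 1])
        assert r.auc == 0.5


class TestDeLong:
    def test_self_comparison_p_one(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        c = delong_compare(scores, scores, labels)
        assert c.auc_difference == 0.0
        assert c.p == 1.0

    def test_structural_component_enumeration_oracle(self):
        """Variance and covariance match direct placement enumeration on a
        6-subject paired toy set."""
        labels = np.array([0, 0, 0, 1, 1, 1])
        a = np.array([0.2, 0.5, 0.5, 0.4, 0.9, 0.7])
        b = np.array([0.1, 0.8, 0.3, 0.6, 0.6, 0.9])
        pos, neg = slice(3, 6), slice(0, 3)

        def placements(x):
            v10 = [np.mean([(xp > xn) + 0.5 * (xp == xn) for xn in x[neg]])
                   for xp in x[pos]]
            v01 = [np.mean([(xp > xn) + 0.5 * (xp == xn) for xp in x[pos]])
                   for xn in x[neg]]
            return np.array(v10), np.array(v01)

        v10a, v01a = placements(a)
        v10b, v01b = placements(b)
        auc_a, auc_b = v10a.mean(), v10b.mean()
        var = (np.var(v10a, ddof=1) + np.var(v10b, ddof=1)) / 3 \
            + (np.var(v01a, ddof=1) + np.var(v01b, ddof=1)) / 3
        cov = np.cov(v10a, v10b, ddof=1)[0, 1] / 3 \
            + np.cov(v01a, v01b, ddof=1)[0, 1] / 3
        z_expected = (auc_a - auc_b) / np.sqrt(var - 2 * cov)

        c = delong_compare(a, b, labels)
        assert c.marker_a.auc == pytest.approx(auc_a)
        assert c.marker_b.auc == pytest.approx(auc_b)
        assert c.z == pytest.approx(z_expected)
        assert c.p == pytest.approx(2 * stats.norm.sf(abs(z_expected)))

    def test_matches_frozen_proc_reference(self):
        """Values cross-checked against an independent DeLong implementation
        (pROC 1.19, R 4.3) on this fixture, frozen to 10 decimals."""
        labels = [0] * 8 + [1] * 8
        a = [0.2, 1.1, 0.7, 0.4, 1.5, 0.3, 0.9, 0.6,
             1.2, 2.3, 0.8, 1.9, 2.8, 1.4, 2.1, 1.0]
        b = [0.5, 0.9, 1.3, 0.2, 1.1, 0.8, 0.4, 0.7,
             1.0, 1.2, 2.2, 0.9, 1.8, 2.5, 1.1, 0.3]
        ra = auc(a, labels)
        assert ra.auc == pytest.approx(0.8906250000, abs=1e-10)
        assert ra.se ** 2 == pytest.approx(0.0066266741, abs=1e-9)
        assert ra.ci_low == pytest.approx(0.7310753347, abs=1e-9)
        assert ra.ci_high == 1.0
        c = delong_compare(a, b, labels)
        assert c.marker_b.auc == pytest.approx(0.7812500000, abs=1e-10)
        assert c.z == pytest.approx(0.8332658542, abs=1e-9)
        assert c.p == pytest.approx(0.4046948093, abs=1e-9)

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_compare([1, 2, 3], [1, 2], [0, 1, 1])

    def test_zero_variance_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateComparisonError):
            delong_compare([0, 1], [1, 0], [0, 1])

    def test_auc_from_components_equals_mann_whitney(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.integers(0, 5, size=30).astype(float)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert auc(scores, labels).auc == pytest.approx(
                u / (len(pos) * len(neg)))


class TestYouden:
    def test_separated_classes_midpoint(self):
        cutoff, sens, spec = youden_cutoff([0, 0, 1, 3, 4, 4], [0, 0, 0, 1, 1, 1])
        assert cutoff == 2.0
        assert sens == 100.0
        assert spec == 100.0

    @given(st.lists(st.integers(0, 8), min_size=3, max_size=10),
           st.lists(st.integers(0, 8), min_size=3, max_size=10))
    def test_equals_exhaustive_search(self, neg, pos):
        scores = np.array(neg + pos, dtype=float)
        labels = np.array([0] * len(neg) + [1] * len(pos))
        if np.ptp(scores) == 0:
            return
        cutoff, sens, spec = youden_cutoff(scores, labels)
        distinct = np.unique(scores)
        best_j = -np.inf
        for c in (distinct[:-1] + distinct[1:]) / 2:
            s = 100 * np.mean(scores[labels == 1] >= c)
            sp = 100 * np.mean(scores[labels == 0] < c)
            best_j = max(best_j, s + sp - 100)
        assert sens + spec - 100 == pytest.approx(best_j)

    def test_tie_broken_toward_higher_specificity(self):
        # J = 0.5 at cutoffs 0.5 and 2.5; the more specific one wins
        scores = [0, 1, 2, 3]
        labels = [0, 1, 0, 1]
        cutoff, sens, spec = youden_cutoff(scores, labels)
        assert cutoff == 2.5
        assert spec == 100.0
        assert sens == 50.0

    def test_monotone_transform_preserves_operating_point(self):
        scores = np.array([0, 1, 2, 2, 3, 5, 6, 8], dtype=float)
        labels = [0, 0, 0, 1, 0, 1, 1, 1]
        _, sens, spec = youden_cutoff(scores, labels)
        _, sens_t, spec_t = youden_cutoff(scores ** 3 + 1, labels)
        assert (sens, spec) == (sens_t, spec_t)


class TestIcc:
    def rating_table(self, seed=3, n=12):
        rng = np.random.default_rng(seed)
        subj = rng.normal(10, 3, size=(n, 1))
        return subj + rng.normal(0, 1, size=(n, 2))

    def test_identical_raters_exact_one(self):
        x = self.rating_table()
        x[:, 1] = x[:, 0]
        for definition in ("agreement", "consistency"):
            res = icc_two_way(x, definition)
            assert res.icc == 1.0
            assert res.ci_low == res.ci_high == 1.0

    def test_constant_shift_distinguishes_definitions(self):
        x = self.rating_table()
        x[:, 1] = x[:, 0] + 2.0
        assert icc_two_way(x, "consistency").icc == pytest.approx(1.0)
        assert icc_two_way(x, "agreement").icc < 1.0

    def test_mean_squares_oracle_six_by_two(self):
        """Hand-computable 6x2 table: ICC from explicit variance components."""
        x = np.array([[7, 9], [5, 6], [8, 8], [2, 4], [9, 10], [4, 5]], float)
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1)[:, None] - x.mean(0)[None, :] + grand) ** 2
               ).sum() / ((n - 1) * (k - 1))
        expected_c = (msr - mse) / (msr + (k - 1) * mse)
        expected_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_two_way(x, "consistency").icc == pytest.approx(expected_c)
        assert icc_two_way(x, "agreement").icc == pytest.approx(expected_a)

    def test_matches_pingouin(self):
        import pingouin as pg
        x = self.rating_table(seed=11)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(len(x)), 2),
            "rater": np.tile([0, 1], len(x)),
            "score": x.ravel()})
        table = pg.intraclass_corr(df, "subject", "rater", "score")
        ref = table.set_index("Type")
        for definition, key in (("agreement", "ICC(A,1)"),
                                ("consistency", "ICC(C,1)")):
            mine = icc_two_way(x, definition)
            assert mine.icc == pytest.approx(float(ref.loc[key, "ICC"]), abs=1e-9)
            lo, hi = ref.loc[key, "CI95"]
            assert mine.ci_low == pytest.approx(lo, abs=0.011)
            assert mine.ci_high == pytest.approx(hi, abs=0.011)

    def test_subject_permutation_invariant(self):
        x = self.rating_table(seed=4)
        perm = np.random.default_rng(0).permutation(len(x))
        a = icc_two_way(x, "agreement")
        b = icc_two_way(x[perm], "agreement")
        assert a.icc == pytest.approx(b.icc)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_missing_cells_and_small_n_rejected(self):
        x = self.rating_table()
        x[0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_two_way(x)
        with pytest.raises(ValueError, match="5 subjects"):
            icc_two_way(self.rating_table(n=4))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_ci(x, x).r == pytest.approx(1.0)
        assert pearson_ci(x, -x).r == pytest.approx(-1.0)

    def test_definitional_formula_ten_pairs(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = 0.6 * x + rng.normal(size=10)
        r_def = (np.mean((x - x.mean()) * (y - y.mean()))
                 / (x.std(ddof=0) * y.std(ddof=0)))
        res = pearson_ci(x, y)
        assert res.r == pytest.approx(r_def)
        # Fisher z interval recomputed directly
        z = np.arctanh(res.r)
        half = stats.norm.ppf(0.975) / np.sqrt(10 - 3)
        assert res.ci_low == pytest.approx(np.tanh(z - half), abs=1e-9)
        assert res.ci_high == pytest.approx(np.tanh(z + half), abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])

    @pytest.mark.parametrize("r, label", [
        (0.1, "very weak"), (-0.25, "weak"), (0.55, "moderate"),
        (0.7, "strong"), (-0.9, "excellent")])
    def test_evans_bands(self, r, label):
        assert evans_strength(r) == label


class TestGroupCompare:
    def cohort(self, n=60, seed=8, groups=("HC", "MCI", "AD")):
        rng = np.random.default_rng(seed)
        g = np.repeat(groups, n)
        age = rng.normal(78, 6, size=len(g))
        shift = {"HC": 0.0, "MCI": 10.0, "AD": 20.0}
        y = np.array([shift[x] for x in g]) + 0.2 * (age - 78) \
            + rng.normal(0, 5, size=len(g))
        return pd.DataFrame({"group": g, "age": age, "outcome": y})

    def test_reduces_to_one_way_anova_without_covariates(self):
        df = self.cohort(groups=("HC", "AD"))
        gc = group_compare(df, "outcome")
        f_ref, p_ref = stats.f_oneway(
            df.loc[df.group == "HC", "outcome"],
            df.loc[df.group == "AD", "outcome"])
        assert gc.f_statistic == pytest.approx(f_ref)
        assert gc.p == pytest.approx(p_ref)

    def test_uncorrelated_covariate_leaves_means_nearly_raw(self):
        rng = np.random.default_rng(1)
        df = self.cohort(n=2000, groups=("HC", "AD"))
        df["noise"] = rng.normal(size=len(df))  # independent of group
        gc = group_compare(df, "outcome", covariates=["noise"])
        raw = df.groupby("group")["outcome"].mean()
        for g in ("HC", "AD"):
            assert gc.adjusted_means[g] == pytest.approx(raw[g], abs=0.15)

    def test_three_groups_bonferroni_arithmetic(self):
        df = self.cohort()
        gc = group_compare(df, "outcome", covariates=["age"])
        assert len(gc.pairwise) == 3
        import statsmodels.formula.api as smf
        model = smf.ols("outcome ~ C(group) + age", data=df).fit()
        raw_p = float(model.t_test("C(group)[T.MCI]").pvalue)
        (p_hc_mci,) = [p for a, b, _, p in gc.pairwise
                       if {a, b} == {"HC", "MCI"}]
        assert p_hc_mci == pytest.approx(min(1.0, 3 * raw_p))

    def test_adjusted_means_order_preserved(self):
        gc = group_compare(self.cohort(), "outcome", covariates=["age"])
        assert gc.adjusted_means["HC"] < gc.adjusted_means["MCI"] \
            < gc.adjusted_means["AD"]

    def test_collinear_covariate_named(self):
        df = self.cohort()
        df["age_copy"] = df["age"] * 2
        with pytest.raises(ValueError, match="age_copy"):
            group_compare(df, "outcome", covariates=["age", "age_copy"])


class TestValidityReport:
    def separated_cohort(self):
        rows = []
        for i in range(10):
            rows.append({"participant_id": f"H{i}", "group": "HC",
                         "b_adl_di": 0.0 + i * 0.1, "i_adl_di": i * 0.2,
                         "katz_total": 6, "lawton_total": 27})
        for i in range(10):
            rows.append({"participant_id": f"A{i}", "group": "AD",
                         "b_adl_di": 50.0 + i, "i_adl_di": 60.0 + i,
                         "katz_total": 20, "lawton_total": 9})
        return pd.DataFrame(rows)

    def test_perfect_markers_auc_one_and_p_one(self):
        rep = validity_report(self.separated_cohort(),
                              comparisons=[("HC", "AD")])
        assert (rep["auc"] == 1.0).all()
        markers = rep[rep["reference"].notna()]
        assert (markers["delong_p"] == 1.0).all()

    def test_missing_reference_warns_and_omits(self):
        df = self.separated_cohort().drop(columns=["lawton_total"])
        with pytest.warns(UserWarning, match="lawton_total"):
            rep = validity_report(df, comparisons=[("HC", "AD")])
        i_rows = rep[rep.marker == "i_adl_di"]
        assert i_rows["delong_p"].isna().all()

    def test_lawton_cutoff_reported_in_native_units(self):
        rep = validity_report(self.separated_cohort(),
                              comparisons=[("HC", "AD")])
        row = rep[rep.marker == "lawton_total"].iloc[0]
        assert 9 <= row["cutoff"] <= 27

    def test_deterministic(self):
        df = self.separated_cohort()
        a = validity_report(df, comparisons=[("HC", "AD")])
        b = validity_report(df, comparisons=[("HC", "AD")])
        pd.testing.assert_frame_equal(a, b)
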