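"""Regression/ANOVA against brute-force oracles; Newman-Keuls letters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import rhodolith as rh
from rhodolith.errors import InsufficientReplicationError


class TestRegression:
    def test_exact_line(self):
        res = rh.linear_regression([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_matches_brute_force_normal_equations(self, rng):
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(size=12)
        res = rh.linear_regression(x, y)
        # closed-form OLS
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        se = np.sqrt(np.sum(resid**2) / (len(x) - 2) / sxx)
        t = slope / se
        p = 2 * sps.t.sf(abs(t), len(x) - 2)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)
        assert res.r2 == pytest.approx(r2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_confidence_band_contains_fitted_line(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 2 + 0.5 * x + rng.normal(0, 1, 15)
        res = rh.linear_regression(x, y)
        band = res.conf_band
        assert np.all(band.lower <= band.fit + 1e-12)
        assert np.all(band.fit <= band.upper + 1e-12)
        assert np.allclose(band.fit, res.predict(band.x))

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            rh.linear_regression([2, 2, 2, 2], [1, 2, 3, 4])

    def test_null_slope_p_values_are_uniform(self, rng):
        """Type-I behaviour: under the null, slope p ~ U(0,1)."""
        pvals = [rh.linear_regression(rng.normal(size=8),
                                      rng.normal(size=8)).p_value
                 for _ in range(400)]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = rh.one_way_anova([[1.0, 2, 3], [1.0, 2, 3], [1.0, 2, 3]])
        assert res.terms[0].F == 0.0
        assert res.terms[0].p == pytest.approx(1.0)

    def test_textbook_example_matches_hand_sums_of_squares(self):
        groups = [np.array([6.0, 8, 4, 5, 3]),
                  np.array([8.0, 12, 9, 11, 6]),
                  np.array([13.0, 9, 11, 8, 7])]
        res = rh.one_way_anova(groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(5 * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 12)
        assert res.terms[0].F == pytest.approx(f_hand, rel=1e-12)
        assert (res.terms[0].df1, res.terms[0].df2) == (2, 12)
        # independent implementation
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.terms[0].F == pytest.approx(f_ref, rel=1e-12)
        assert res.terms[0].p == pytest.approx(p_ref, rel=1e-9)

    def test_summary_statistics_simulation_near_reported_f(self):
        """Groups drawn at the reported gross-photosynthesis means/SEs (n=5)
        produce F statistics scattered around the reported value."""
        rng = np.random.default_rng(5)
        means, se, n = (0.50, 0.61, 0.52), 0.027, 5
        fs = []
        for _ in range(200):
            groups = [rng.normal(m, se * np.sqrt(n), n) for m in means]
            fs.append(rh.one_way_anova(groups).terms[0].F)
        fs = np.array(fs)
        assert np.percentile(fs, 10) < 5.11 < np.percentile(fs, 90)

    def test_insufficient_replication_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            rh.one_way_anova([[1.0], [2.0]])


class TestTwoWayAnova:
    @staticmethod
    def _hand_two_way(df):
        """Brute-force balanced two-way SS decomposition."""
        grand = df.y.mean()
        n = len(df)
        a_means = df.groupby("a").y.mean()
        b_means = df.groupby("b").y.mean()
        cell_means = df.groupby(["a", "b"]).y.mean()
        n_per_a = df.groupby("a").size()
        n_per_b = df.groupby("b").size()
        n_cell = df.groupby(["a", "b"]).size()
        ss_a = float((n_per_a * (a_means - grand) ** 2).sum())
        ss_b = float((n_per_b * (b_means - grand) ** 2).sum())
        ss_cells = float((n_cell * (cell_means - grand) ** 2).sum())
        ss_ab = ss_cells - ss_a - ss_b
        resid = df.y - df.set_index(["a", "b"]).index.map(cell_means)
        ss_e = float((resid**2).sum())
        df_a = df.a.nunique() - 1
        df_b = df.b.nunique() - 1
        df_ab = df_a * df_b
        df_e = n - df.a.nunique() * df.b.nunique()
        mse = ss_e / df_e
        return (ss_a / df_a / mse, ss_b / df_b / mse, ss_ab / df_ab / mse)

    def test_balanced_toy_table_matches_hand_decomposition(self, rng):
        rows = [{"a": a, "b": b, "y": rng.normal()}
                for a in "xy" for b in "uvw" for _ in range(4)]
        df = pd.DataFrame(rows)
        res = rh.two_way_anova(df, "y", "a", "b")
        f_a, f_b, f_ab = self._hand_two_way(df)
        assert res.term("a").F == pytest.approx(f_a, rel=1e-9)
        assert res.term("b").F == pytest.approx(f_b, rel=1e-9)
        assert res.term("a:b").F == pytest.approx(f_ab, rel=1e-9)

    def test_balanced_null_data_not_significant(self, rng):
        rows = [{"a": a, "b": b, "y": rng.normal()}
                for a in "xy" for b in "uv" for _ in range(6)]
        res = rh.two_way_anova(pd.DataFrame(rows), "y", "a", "b")
        assert all(t.p > 0.01 for t in res.terms)

    def test_injected_interaction_detected(self, rng):
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                shift = 2.0 if (a == b == 1) else 0.0
                rows += [{"a": a, "b": b, "y": rng.normal(shift, 0.5)}
                         for _ in range(6)]
        res = rh.two_way_anova(pd.DataFrame(rows), "y", "a", "b")
        assert res.term("a:b").p < 0.01

    def test_missing_cell_rejected(self):
        df = pd.DataFrame({"a": ["x", "x", "y", "y"], "b": ["u", "u", "u", "u"],
                           "y": [1.0, 2, 3, 4]})
        df = pd.concat([df, pd.DataFrame({"a": ["x"], "b": ["v"], "y": [2.0]})])
        with pytest.raises(InsufficientReplicationError):
            rh.two_way_anova(df, "y", "a", "b")

    def test_unbalanced_design_warns(self, rng):
        rows = [{"a": a, "b": b, "y": rng.normal()}
                for a in "xy" for b in "uv" for _ in range(4)]
        rows.append({"a": "x", "b": "u", "y": 0.0})
        with pytest.warns(UserWarning):
            rh.two_way_anova(pd.DataFrame(rows), "y", "a", "b")


def brute_force_nk(groups, alpha=0.05):
    """All-pairs studentized range at the full span (oracle for clear cases)."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    an = rh.one_way_anova(groups)
    sig = set()
    means = [g.mean() for g in groups]
    order = np.argsort(means)
    ranks = {g: r for r, g in enumerate(order)}
    for i in range(k):
        for j in range(i + 1, k):
            span = abs(ranks[i] - ranks[j]) + 1
            se = np.sqrt(an.mse / 2 * (1 / len(groups[i]) + 1 / len(groups[j])))
            q = abs(means[i] - means[j]) / se
            if q >= sps.studentized_range.ppf(1 - alpha, span, an.df_error):
                sig.add((i, j))
    return sig


class TestNewmanKeuls:
    def test_single_outlying_mean_gets_its_own_letter(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(0.1, 1, 6), rng.normal(9, 1, 6)]
        res = rh.newman_keuls(groups)
        assert res.group_labels == ("a", "a", "b")
        assert res.significant_pairs == frozenset(brute_force_nk(groups))

    def test_identical_groups_share_one_letter(self):
        groups = [np.array([1.0, 2, 3, 4])] * 3
        assert rh.newman_keuls(groups).group_labels == ("a", "a", "a")

    def test_three_separated_groups_get_three_letters(self, rng):
        groups = [rng.normal(m, 0.02, 5) for m in (0.12, 0.19, 0.08)]
        res = rh.newman_keuls(groups)
        assert res.group_labels == ("a", "b", "c")

    def test_matches_all_pairs_oracle_on_random_instances(self, rng):
        """Where the stepwise and all-pairs procedures agree (the usual case
        for well-separated or fully-null instances), letters must encode
        exactly the significant pairs."""
        for trial in range(20):
            k = int(rng.integers(3, 6))
            spread = rng.choice([0.0, 3.0])
            groups = [rng.normal(spread * i, 1.0, 6) for i in range(k)]
            res = rh.newman_keuls(groups)
            # letters encode non-significance: groups share a letter
            # iff the procedure did not separate them
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(set(res.group_labels[i]) & set(res.group_labels[j]))
                    sep = (i, j) in res.significant_pairs
                    assert share != sep, (trial, i, j, res.group_labels)

    def test_letters_assigned_in_group_input_order(self, rng):
        # rate tables print superscripts column by column, so the first
        # group takes "a" whatever its rank among the means
        groups = [rng.normal(9, 0.5, 6), rng.normal(0, 0.5, 6)]
        res = rh.newman_keuls(groups)
        assert res.group_labels == ("a", "b")


class TestAssumptionChecks:
    def test_well_behaved_normal_samples_pass(self, rng):
        """Each check is non-significant in >= 90 % of null replicates."""
        levene_ok = 0
        shapiro_ps = []
        for _ in range(30):
            groups = [rng.normal(0, 1, 50) for _ in range(3)]
            rep = rh.assumption_checks(groups)
            levene_ok += rep.homoscedastic
            shapiro_ps.extend(rep.shapiro_p)
        assert levene_ok >= 27
        assert np.mean(np.asarray(shapiro_ps) > 0.05) >= 0.90

    def test_variance_ratio_detected_by_levene(self, rng):
        groups = [rng.normal(0, 1, 30), rng.normal(0, 10, 30)]
        assert rh.assumption_checks(groups).levene_p < 0.01

    def test_constant_data_flagged_without_crashing(self):
        rep = rh.assumption_checks([[1.0, 1, 1, 1], [2.0, 2, 2, 2]])
        assert rep.degenerate
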