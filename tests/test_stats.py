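import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from needledyn import stats as nds
from needledyn.stats import (
    StepwiseModel,
    UnbalancedDesignError,
    compact_letter_display,
    durbin_watson,
    kw_mw_battery,
    pairwise_t_bonferroni,
    pca,
    rm_anova,
    stepwise_regression,
)


def _long(values, treatments, days, subjects, times=None):
    rows = []
    for i, v in enumerate(values):
        row = {"value": v, "treatment": treatments[i], "day": days[i],
               "subject": subjects[i]}
        if times is not None:
            row["time"] = times[i]
        rows.append(row)
    return pd.DataFrame(rows)


def toy_mixed_table():
    """2 treatments x 2 days x 3 subjects each, hand-checkable numbers."""
    data = {
        ("A", "s1"): {1: 10.0, 2: 12.0},
        ("A", "s2"): {1: 11.0, 2: 14.0},
        ("A", "s3"): {1: 9.0, 2: 13.0},
        ("B", "s4"): {1: 20.0, 2: 19.0},
        ("B", "s5"): {1: 22.0, 2: 18.0},
        ("B", "s6"): {1: 21.0, 2: 23.0},
    }
    rows = []
    for (treat, subj), days in data.items():
        for day, v in days.items():
            rows.append({"treatment": treat, "subject": subj, "day": day, "value": v})
    return pd.DataFrame(rows)


def brute_mixed_ss(df):
    """Cell-means mixed-ANOVA decomposition written out longhand."""
    gm = df.value.mean()
    a = df.treatment.nunique()
    d = df.day.nunique()
    n = df.subject.nunique() // a
    m_subj = df.groupby("subject").value.mean()
    m_T = df.groupby("treatment").value.mean()
    m_D = df.groupby("day").value.mean()
    m_TD = df.groupby(["treatment", "day"]).value.mean()
    ss_T = d * n * sum((m_T - gm) ** 2)
    ss_between = d * sum((m_subj - gm) ** 2)
    ss_subjT = ss_between - ss_T
    ss_D = a * n * sum((m_D - gm) ** 2)
    ss_TD = n * sum(
        (m_TD[t, dd] - m_T[t] - m_D[dd] + gm) ** 2
        for t in m_T.index for dd in m_D.index
    )
    ss_total = sum((df.value - gm) ** 2)
    ss_err = ss_total - ss_between - ss_D - ss_TD
    return dict(T=ss_T, subjT=ss_subjT, D=ss_D, TD=ss_TD, err=ss_err)


class TestRmAnova:
    def test_toy_table_matches_hand_decomposition(self):
        df = toy_mixed_table()
        res = rm_anova(df, within=["day"]).table.set_index("effect")
        brute = brute_mixed_ss(df)
        assert res.loc["treatment", "SS"] == pytest.approx(brute["T"])
        assert res.loc["subject(treatment)", "SS"] == pytest.approx(brute["subjT"])
        assert res.loc["day", "SS"] == pytest.approx(brute["D"])
        assert res.loc["day:treatment", "SS"] == pytest.approx(brute["TD"])
        assert res.loc["day:subject(treatment)", "SS"] == pytest.approx(brute["err"])
        assert res.loc["treatment", "df"] == 1
        assert res.loc["subject(treatment)", "df"] == 4
        assert res.loc["day:subject(treatment)", "df"] == 4

    def test_matches_pingouin_mixed_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        rows = []
        for t_i, treat in enumerate(("ctl", "dro")):
            for s in range(6):
                subj = f"{treat}{s}"
                for day in range(3):
                    rows.append(
                        {"treatment": treat, "subject": subj, "day": day,
                         "value": rng.normal(t_i * 2 + day * 0.5, 1.0)}
                    )
        df = pd.DataFrame(rows)
        mine = rm_anova(df, within=["day"]).table.set_index("effect")
        theirs = pingouin.mixed_anova(
            data=df, dv="value", within="day", subject="subject", between="treatment"
        ).set_index("Source")
        assert mine.loc["treatment", "F"] == pytest.approx(
            theirs.loc["treatment", "F"], rel=1e-6
        )
        assert mine.loc["day", "F"] == pytest.approx(theirs.loc["day", "F"], rel=1e-6)
        assert mine.loc["day:treatment", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-6
        )
        assert mine.loc["treatment", "p"] == pytest.approx(
            theirs.loc["treatment", "p_unc"], rel=1e-6
        )

    def test_three_way_df_and_total_ss(self, rng):
        rows = []
        for treat in ("c", "d"):
            for s in range(4):
                subj = f"{treat}{s}"
                for day in range(3):
                    for time in ("M", "E"):
                        rows.append(
                            {"treatment": treat, "subject": subj, "day": day,
                             "time": time, "value": rng.normal()}
                        )
        df = pd.DataFrame(rows)
        tab = rm_anova(df, within=["day", "time"]).table
        assert int(tab.df.sum()) == len(df) - 1
        gm = df.value.mean()
        assert tab.SS.sum() == pytest.approx(((df.value - gm) ** 2).sum())
        assert (tab.SS >= 0).all()

    def test_zero_variance_gives_nan_f(self):
        df = toy_mixed_table()
        df["value"] = 5.0
        tab = rm_anova(df, within=["day"]).table
        assert (tab.SS == 0).all()
        assert tab[~tab.is_error].F.isna().all()

    def test_missing_cell_rejected(self):
        df = toy_mixed_table().iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            rm_anova(df, within=["day"])

    def test_unequal_groups_rejected(self):
        df = toy_mixed_table()
        extra = pd.DataFrame(
            [{"treatment": "A", "subject": "s7", "day": 1, "value": 1.0},
             {"treatment": "A", "subject": "s7", "day": 2, "value": 2.0}]
        )
        with pytest.raises(UnbalancedDesignError):
            rm_anova(pd.concat([df, extra]), within=["day"])

    def test_null_calibration_quick(self, rng):
        # a reduced-rep calibration; the full 1000-rep run lives in acceptance
        rejections = 0
        reps = 200
        for _ in range(reps):
            rows = []
            for treat in ("c", "d"):
                for s in range(8):
                    subj = f"{treat}{s}"
                    for day in range(3):
                        rows.append({"treatment": treat, "subject": subj,
                                     "day": day, "value": rng.normal()})
            tab = rm_anova(pd.DataFrame(rows), within=["day"]).table.set_index("effect")
            if tab.loc["treatment", "p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09


class TestPairwiseT:
    def test_identical_groups_share_letter(self):
        df = pd.DataFrame(
            {"group": ["a"] * 5 + ["b"] * 5, "value": [1.0, 2, 3, 4, 5] * 2}
        )
        res = pairwise_t_bonferroni(df, group="group")
        assert res.comparisons.p_adj.iloc[0] == 1.0
        assert res.letters["a"] == res.letters["b"]

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "group": np.repeat(list("abcd"), 10),
                "value": rng.normal(size=40),
            }
        )
        res = pairwise_t_bonferroni(df, group="group")
        m = len(res.comparisons)
        assert m == 6
        for r in res.comparisons.itertuples():
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * m))
            assert r.p_adj >= r.p_raw

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": np.repeat(list("abc"), 10),
                "value": np.concatenate(
                    [rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10),
                     rng.normal(10, 0.1, 10)]
                ),
            }
        )
        res = pairwise_t_bonferroni(df, group="group")
        letters = res.letters
        assert len({letters["a"], letters["b"], letters["c"]}) == 3

    def test_paired_uses_subject_alignment(self):
        df = pd.DataFrame(
            {
                "group": ["d1"] * 4 + ["d2"] * 4,
                "subject": list("wxyz") * 2,
                "value": [1.0, 2, 3, 4, 2.0, 3, 4, 5],  # constant +1 shift
            }
        )
        res = pairwise_t_bonferroni(df, group="group", subject="subject", paired=True)
        unpaired = pairwise_t_bonferroni(df, group="group")
        # the within-subject shift is perfectly consistent: paired p is tiny
        assert res.comparisons.p_raw.iloc[0] < 1e-6
        assert unpaired.comparisons.p_raw.iloc[0] > 0.1

    def test_small_group_excluded_with_warning(self):
        df = pd.DataFrame(
            {"group": ["a", "b", "b", "c", "c"], "value": [1.0, 2, 3, 4, 5]}
        )
        with pytest.warns(UserWarning, match="n < 2"):
            res = pairwise_t_bonferroni(df, group="group")
        assert set(res.letters) == {"b", "c"}


class TestCompactLetterDisplay:
    def test_forced_assignment(self):
        sig = {("A", "B"): True, ("A", "C"): True, ("B", "C"): False}
        letters = compact_letter_display(["A", "B", "C"], sig)
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["B"])
        assert not set(letters["A"]) & set(letters["C"])

    def test_all_nonsignificant_share(self):
        letters = compact_letter_display(list("PQR"), {})
        assert letters["P"] == letters["Q"] == letters["R"]

    def test_random_matrices_sharing_equals_significance(self, rng):
        for _ in range(50):
            groups = list("abcde")
            sig = {}
            for ga, gb in itertools.combinations(groups, 2):
                sig[(ga, gb)] = bool(rng.random() < 0.4)
            letters = compact_letter_display(groups, sig)
            for (ga, gb), s in sig.items():
                share = bool(set(letters[ga]) & set(letters[gb]))
                assert share != s, (sig, letters)
            assert all(letters[g] for g in groups)


class TestKwMwBattery:
    def test_identical_groups(self):
        res = kw_mw_battery({"a": [1.0, 1, 1], "b": [1.0, 1, 1]})
        assert res.omnibus["H"] == 0.0
        assert res.omnibus["p"] == 1.0
        assert res.comparisons.empty

    def test_enumeration_oracle(self):
        # U=0 for {1,2,3} vs {4,5,6}; exact two-sided p = 2 * 1/C(6,3) = 0.1
        res = kw_mw_battery({"lo": [1.0, 2, 3], "hi": [4.0, 5, 6]})
        assert res.omnibus["p"] < 0.05
        row = res.comparisons.iloc[0]
        assert row.statistic in (0.0, 9.0)  # U of first sample or its complement
        assert row.p_raw == pytest.approx(0.1)

    def test_exact_p_matches_full_enumeration(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(size=4) + 0.5
        _, p_scipy = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        # brute-force: enumerate all C(8,4) group assignments of the pooled data
        pooled = np.concatenate([x, y])
        u_obs, _ = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        n = len(pooled)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), 4):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(n) if i not in idx]]
            u, _ = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
            nm = len(xs) * len(ys)
            if min(u, nm - u) <= min(u_obs, nm - u_obs):
                count += 1
            total += 1
        assert p_scipy == pytest.approx(count / total)

    def test_injected_shift_flagged(self):
        rng = np.random.default_rng(3)
        groups = {
            "CM": rng.normal(0, 1, 10), "CE": rng.normal(0, 1, 10),
            "DM": rng.normal(0, 1, 10), "DE": rng.normal(6, 1, 10),
        }
        res = kw_mw_battery(groups)
        assert res.omnibus["p"] < 0.05
        comp = res.comparisons.set_index(["group_a", "group_b"])
        for pair in [("CE", "DE"), ("CM", "DE")]:
            assert comp.loc[pair, "p_adj"] < 0.05
        assert not set(res.letters["DE"]) & set(res.letters["CM"])


class TestStepwise:
    def test_exact_fit_selects_only_true_predictor(self, rng):
        n = 50
        x1 = rng.normal(size=n)
        X = pd.DataFrame(
            {"x1": x1, "d1": rng.normal(size=n), "d2": rng.normal(size=n),
             "d3": rng.normal(size=n)}
        )
        y = 3.0 + 2.0 * x1
        model = stepwise_regression(y, X)
        assert model.predictors == ["x1"]
        assert model.r2 == pytest.approx(1.0)
        assert model.coefficients["x1"] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(3.0)
        assert model.vif["x1"] == pytest.approx(1.0)

    def test_pure_noise_entry_rate(self, rng):
        entries = 0
        reps = 300
        for _ in range(reps):
            X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
            y = rng.normal(size=30)
            model = stepwise_regression(y, X, entry_p=0.05)
            entries += len(model.predictors)
        rate = entries / (2 * reps)
        assert 0.02 <= rate <= 0.09

    def test_enter_all_with_permissive_thresholds(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        model = stepwise_regression(y, X, entry_p=1.0, removal_p=1.0)
        assert set(model.predictors) == {"a", "b", "c"}

    def test_entry_p_zero_gives_intercept_only(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] * 5 + rng.normal(size=40)
        model = stepwise_regression(y, X, entry_p=1e-300)
        assert model.predictors == []
        assert model.intercept == pytest.approx(float(np.mean(y)))

    def test_collinear_candidate_skipped(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"x": x, "x_copy": 2 * x + 1, "z": rng.normal(size=40)})
        y = 4 * x + rng.normal(0, 0.1, size=40)
        with pytest.warns(UserWarning, match="collinear"):
            model = stepwise_regression(y, X, entry_p=1.0, removal_p=1.0)
        # exactly one of the two perfectly collinear copies may enter
        assert len({"x", "x_copy"} & set(model.predictors)) == 1

    def test_diagnostics_invariants(self, rng):
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = 1 + X["a"] - 2 * X["b"] + rng.normal(0, 0.5, size=n)
        model = stepwise_regression(y, X)
        assert 0 <= model.r2 <= 1
        assert model.adj_r2 <= model.r2
        for c in model.predictors:
            assert model.vif[c] == pytest.approx(1.0 / model.tolerance[c])

    def test_standardized_beta_scale_invariant(self, rng):
        n = 80
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = 1 + 2 * a - b + rng.normal(0, 0.5, size=n)
        m1 = stepwise_regression(y, pd.DataFrame({"a": a, "b": b}))
        m2 = stepwise_regression(
            y, pd.DataFrame({"a": 100 * a + 7, "b": 0.01 * b - 3})
        )
        for c in ("a", "b"):
            assert m1.std_beta[c] == pytest.approx(m2.std_beta[c], rel=1e-9)

    def test_from_coefficients_linear_predictor(self):
        model = StepwiseModel.from_coefficients(
            9.459, {"Phi_NPQ": -7.098, "LTD": 0.163, "AH_P": -0.046, "SR": -0.004}
        )
        assert model.linear_predictor({}) == pytest.approx(9.459)
        assert model.linear_predictor(
            {"Phi_NPQ": 1.0, "LTD": 2.0, "AH_P": 0.0, "SR": 0.0}
        ) == pytest.approx(9.459 - 7.098 + 0.326)


class TestDurbinWatson:
    def test_alternating_residuals(self):
        assert durbin_watson([1.0, -1, 1, -1]) == pytest.approx(3.0)

    def test_constant_residuals_zero(self):
        assert durbin_watson([1.0, 1, 1, 1]) == pytest.approx(0.0)

    def test_white_noise_near_two(self, rng):
        e = rng.normal(size=20_000)
        assert durbin_watson(e) == pytest.approx(2.0, abs=0.05)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.stattools import durbin_watson as sm_dw

        e = rng.normal(size=100)
        assert durbin_watson(e) == pytest.approx(float(sm_dw(e)), rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson([0.0, 0.0, 0.0])


class TestPca:
    def test_rank_one_line(self):
        x = np.linspace(-1, 1, 50)
        res = pca(np.column_stack([x, x]))
        assert res.proportions[0] == pytest.approx(1.0)

    def test_isotropic_gaussian(self, rng):
        X = rng.normal(size=(20_000, 2))
        res = pca(X)
        assert res.proportions[0] == pytest.approx(0.5, abs=0.02)
        assert res.proportions[1] == pytest.approx(0.5, abs=0.02)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(100, 5)) @ rng.normal(size=(5, 5))
        res = pca(X)
        gram = res.loadings.T @ res.loadings
        assert gram == pytest.approx(np.eye(5), abs=1e-10)

    def test_proportions_sum_to_one(self, rng):
        res = pca(rng.normal(size=(50, 4)))
        assert res.proportions.sum() == pytest.approx(1.0)
        assert np.all(res.proportions >= 0)

    def test_reorder_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        r1 = pca(X)
        r2 = pca(X[list("dcba")])
        assert r1.proportions == pytest.approx(r2.proportions)

    def test_zero_variance_column_dropped(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30),
                          "c": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca(X)
        assert res.columns == ["a", "c"]


class TestGreenhouseGeisser:
    def test_epsilon_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        rows = []
        for t_i, treat in enumerate(("c", "d")):
            for s in range(8):
                base = rng.normal()
                for day in range(4):
                    rows.append(
                        {"treatment": treat, "subject": f"{treat}{s}", "day": day,
                         "value": base + rng.normal() * (1 + day)}
                    )
        df = pd.DataFrame(rows)
        mine = rm_anova(df, within=["day"], gg_correction=True).table.set_index("effect")
        theirs = pingouin.mixed_anova(
            data=df, dv="value", within="day", subject="subject", between="treatment"
        ).set_index("Source")
        # pooling details differ slightly between implementations
        assert mine.loc["day", "eps"] == pytest.approx(
            float(theirs.loc["day", "eps"]), abs=0.05
        )

    def test_correction_never_decreases_p(self, rng):
        rows = [
            {"treatment": t, "subject": f"{t}{s}", "day": d,
             "value": rng.normal() * (1 + d)}
            for t in "cd" for s in range(6) for d in range(4)
        ]
        tab = rm_anova(pd.DataFrame(rows), within=["day"], gg_correction=True).table
        effects = tab[~tab.is_error & tab.stratum.ne("subject")].dropna(subset=["p"])
        # shrinking both df can only hurt effects that beat their error term
        strong = effects[effects.F > 1]
        assert (strong.p_gg >= strong.p - 1e-12).all()
        assert ((effects.eps > 0) & (effects.eps <= 1)).all()

    def test_spherical_data_epsilon_near_one(self, rng):
        rows = [
            {"treatment": t, "subject": f"{t}{s}", "day": d, "value": rng.normal()}
            for t in "cd" for s in range(40) for d in range(3)
        ]
        tab = rm_anova(pd.DataFrame(rows), within=["day"], gg_correction=True).table
        eps = tab.set_index("effect").loc["day", "eps"]
        assert eps > 0.85
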