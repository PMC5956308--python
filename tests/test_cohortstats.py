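"""Group statistics, ROC, stepwise logistic selection and LOOCV."""

import numpy as np
import pandas as pd
import pytest

from nailfold import cohortstats as cs
from nailfold.errors import InvalidInputError, SchemaError


def make_table(values_by_group, fill=0.5):
    rows = []
    i = 0
    for g, vals in values_by_group.items():
        for v in vals:
            row = {"subject_id": f"s{i:03d}", "group": g}
            row.update({p: fill for p in cs.PARAMETERS})
            row["density"] = float(v)
            rows.append(row)
            i += 1
    return cs.CohortTable(pd.DataFrame(rows))


def exhaustive_auc(scores, labels):
    """Independent oracle: count every positive/negative pair."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestCohortTable:
    def test_schema_enforced(self):
        with pytest.raises(SchemaError):
            cs.CohortTable(pd.DataFrame({"subject_id": ["a"], "group": ["HC"]}))

    def test_row_order_invariance(self):
        t = cs.simulate_cohort_table(8, 4, 8, rng=np.random.default_rng(3))
        shuffled = cs.CohortTable(
            t.df.sample(frac=1.0, random_state=1).reset_index(drop=True))
        assert t.df.equals(shuffled.df)


class TestAnovaTukey:
    def test_hand_computed_f(self):
        """{1,2,3}, {2,3,4}, {5,6,7}: SSB=26, SSW=6 -> F=(26/2)/(6/6)=13."""
        t = make_table({"HC": [1, 2, 3], "PRP": [2, 3, 4], "SSc": [5, 6, 7]})
        res = cs.anova_tukey(t, "density")
        assert res.f_statistic == pytest.approx(13.0, abs=1e-9)
        assert res.pairwise_significant[("SSc", "HC")]
        assert res.pairwise_significant[("SSc", "PRP")]
        assert not res.pairwise_significant[("PRP", "HC")]

    def test_identical_groups_f_zero(self):
        t = make_table({"HC": [2, 2, 2], "PRP": [2, 2, 2], "SSc": [2, 2, 2]})
        res = cs.anova_tukey(t, "density")
        assert res.f_statistic == 0.0
        assert not any(res.pairwise_significant.values())

    def test_matches_scipy_f_oneway(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(5)
        t = make_table({
            "HC": rng.normal(0, 1, 20), "PRP": rng.normal(0.3, 1, 8),
            "SSc": rng.normal(1.0, 1, 15),
        })
        res = cs.anova_tukey(t, "density")
        groups = [t.df.loc[t.df.group == g, "density"] for g in cs.GROUPS]
        ref = f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_group_f_equals_t_squared(self):
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        t = make_table({"HC": a, "SSc": b})
        res = cs.anova_tukey(t, "density")
        tt = ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(tt.statistic ** 2, rel=1e-9)

    def test_tiny_group_rejected(self):
        t = make_table({"HC": [1, 2], "SSc": [3]})
        with pytest.raises(InvalidInputError):
            cs.anova_tukey(t, "density")


class TestRocAuc:
    def test_worked_example(self):
        """Positives {3,1}, negatives {2,0}: 3 wins + 1 loss of 4 pairs."""
        r = cs.roc_auc([3, 1, 2, 0], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_perfect_and_tied(self):
        assert cs.roc_auc([5, 6, 1, 2], [1, 1, 0, 0]).auc == 1.0
        assert cs.roc_auc([3, 3, 3, 3], [1, 1, 0, 0]).auc == 0.5

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(4, 31))
            labels = np.r_[np.ones(max(1, n // 3), int),
                           np.zeros(n - max(1, n // 3), int)]
            rng.shuffle(labels)
            scores = rng.integers(0, 8, size=n).astype(float)
            mine = cs.roc_auc(scores, labels, direction="greater").auc
            assert mine == pytest.approx(exhaustive_auc(scores, labels), abs=1e-12)

    def test_label_flip_complement(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        a = cs.roc_auc(scores, labels, direction="greater").auc
        b = cs.roc_auc(scores, 1 - labels, direction="greater").auc
        assert a + b == pytest.approx(1.0)

    def test_auto_orientation(self):
        # lower scores indicate disease: auto flips to auc >= 0.5
        r = cs.roc_auc([1, 2, 8, 9], [1, 1, 0, 0])
        assert r.auc == 1.0 and r.flipped

    def test_curve_endpoints_and_area(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        r = cs.roc_auc(scores, labels, direction="greater")
        fpr, tpr = r.curve
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            cs.roc_auc([1, 2], [1, 1])


class TestLogisticFit:
    def test_matches_statsmodels(self):
        """The internal Newton solver agrees with the reference ML fit."""
        import statsmodels.api as sm
        rng = np.random.default_rng(21)
        n = 150
        X = rng.normal(size=(n, 3))
        eta = 0.5 + X @ [1.0, -0.7, 0.2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        design = np.column_stack([np.ones(n), X])
        beta, ll, converged, sep = cs._logit_fit(design, y, ridge=0.0)
        ref = sm.Logit(y, design).fit(disp=0)
        assert converged and not sep
        assert beta == pytest.approx(ref.params, abs=1e-6)
        assert ll == pytest.approx(ref.llf, abs=1e-8)


class TestStepwise:
    def _table(self, df):
        return cs.CohortTable(df)

    def test_duplicate_column_not_both_retained(self):
        rng = np.random.default_rng(31)
        n = 200
        x = rng.standard_normal(n)
        y = (x + 0.5 * rng.standard_normal(n) > 0).astype(int)
        df = pd.DataFrame({
            "subject_id": [f"q{i}" for i in range(n)],
            "group": ["SSc" if v else "HC" for v in y],
            "density": x, "mean_width": x.copy(),
            "max_width": rng.standard_normal(n),
            "shape": rng.standard_normal(n),
            "derangement": rng.standard_normal(n),
            "flow": rng.standard_normal(n),
        })
        fit = cs.stepwise_logistic(self._table(df), cs.PARAMETERS)
        assert len({"density", "mean_width"} & set(fit.selected_terms)) <= 1

    def test_informative_parameter_selected(self):
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(200 + s)
            n = 200
            x = rng.standard_normal(n)
            y = (x + 0.5 * rng.standard_normal(n) > 0).astype(int)
            df = pd.DataFrame({
                "subject_id": [f"q{i}" for i in range(n)],
                "group": ["SSc" if v else "HC" for v in y],
                "density": x,
                **{p: rng.standard_normal(n)
                   for p in cs.PARAMETERS if p != "density"},
            })
            fit = cs.stepwise_logistic(self._table(df), cs.PARAMETERS)
            hits += "density" in fit.selected_terms
        assert hits >= 38  # >= 95 %

    def test_null_labels_mostly_empty_selection(self):
        empties = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            tab = cs.null_cohort_table(80, rng)
            fit = cs.stepwise_logistic(tab, cs.PARAMETERS)
            empties += len(fit.selected_terms) == 0
        assert empties >= 10  # plurality of seeds

    def test_constant_column_rejected(self):
        df = cs.null_cohort_table(30, np.random.default_rng(0)).df.copy()
        df["flow"] = 1.0
        with pytest.raises(InvalidInputError):
            cs.stepwise_logistic(cs.CohortTable(df), cs.PARAMETERS)


class TestLoocv:
    def test_score_count_small_cohort(self):
        tab = cs.simulate_cohort_table(4, 2, 4, effect=2.0,
                                       rng=np.random.default_rng(41))
        fit = cs.loocv_roc(tab, cs.PARAMETERS)
        assert len(fit.loocv_scores) == 10
        assert np.isfinite(fit.loocv_scores).sum() == 10

    def test_too_small_rejected(self):
        tab = cs.simulate_cohort_table(3, 2, 3, rng=np.random.default_rng(42))
        with pytest.raises(InvalidInputError):
            cs.loocv_roc(tab, cs.PARAMETERS)

    def test_separated_cohort_high_auc(self):
        tab = cs.simulate_cohort_table(25, 6, 25, effect=3.0,
                                       rng=np.random.default_rng(43))
        fit = cs.loocv_roc(tab, cs.PARAMETERS)
        assert fit.combined_roc.auc >= 0.95


class TestCohortReport:
    def test_report_deterministic_and_order_invariant(self):
        tab = cs.simulate_cohort_table(15, 6, 15, rng=np.random.default_rng(51))
        rep1 = cs.cohort_report(tab)
        shuffled = cs.CohortTable(
            tab.df.sample(frac=1.0, random_state=9).reset_index(drop=True))
        rep2 = cs.cohort_report(shuffled)
        assert rep1.to_json() == rep2.to_json()

    def test_null_cohort_no_flags(self):
        tab = cs.simulate_cohort_table(10, 6, 10, effect=0.0,
                                       rng=np.random.default_rng(52))
        rep = cs.cohort_report(tab)
        n_sig = sum(
            sum(p["pairwise_significant"].values())
            for p in rep.parameters.values()
        )
        assert n_sig <= 2  # alpha-level false positives at most

    def test_table_layout(self):
        tab = cs.simulate_cohort_table(10, 4, 10, rng=np.random.default_rng(53))
        frame = cs.cohort_report(tab).to_dataframe()
        assert list(frame["parameter"][:6]) == list(cs.PARAMETERS)
        assert len(frame) == 8  # six parameters + two combined models
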