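import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import binom

from ribmpr import stats as st


def make_records(n_patients=4, seed=0, prevalence=0.2, miss=0.15, fp=0.01):
    rng = np.random.default_rng(seed)
    rows = []
    types = list(st.FRACTURE_TYPES)
    for p in range(n_patients):
        sex = "M" if rng.random() < 0.6 else "F"
        age = float(rng.uniform(18, 85))
        for side in ("left", "right"):
            for idx in range(1, 13):
                ref = rng.choice(types) if rng.random() < prevalence else "negative"
                if ref != "negative":
                    pred = "negative" if rng.random() < miss else ref
                else:
                    pred = rng.choice(types) if rng.random() < fp else "negative"
                rows.append({"patient": f"P{p:03d}", "side": side,
                             "rib_index": idx, "ref": ref, "pred": pred,
                             "sex": sex, "age": age})
    return pd.DataFrame(rows)


class TestConfusionCounts:
    def test_paper_per_side_counts_pool_to_overall(self):
        left = st.ConfusionCounts("side", "left", tp=473, fn=547 - 473,
                                  fp=29, tn=2213 - 29)
        right = st.ConfusionCounts("side", "right", tp=437, fn=518 - 437,
                                   fp=20, tn=2242 - 20)
        overall = st.pool_counts([left, right])
        assert (overall.tp, overall.fn, overall.fp, overall.tn) == \
            (910, 155, 49, 4406)

    def test_all_negative_records(self):
        df = make_records(2, prevalence=0.0, fp=0.0)
        (c,) = st.confusion_counts(df, "overall")
        assert c.tp == c.fn == c.fp == 0
        assert c.tn == len(df)

    def test_patient_level_any_positive_rule(self):
        df = make_records(1, prevalence=0.0, fp=0.0)
        df.loc[5, "ref"] = "displaced"
        df.loc[5, "pred"] = "buckle"  # detected, even if type differs
        (c,) = st.confusion_counts(df, "patient")
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 0, 0)

    def test_duplicate_keys_rejected(self):
        df = make_records(1)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            st.confusion_counts(dup, "overall")

    @pytest.mark.parametrize("stratifier", ["side", "rib_index", "sex",
                                            "age_group"])
    def test_stratified_counts_sum_to_overall(self, stratifier):
        df = make_records(6, seed=3)
        (overall,) = st.confusion_counts(df, "overall")
        pooled = st.pool_counts(st.confusion_counts(df, stratifier))
        assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == \
            (overall.tp, overall.fp, overall.tn, overall.fn)

    def test_fracture_type_one_vs_rest(self):
        df = make_records(4, seed=5)
        for c in st.confusion_counts(df, "fracture_type"):
            assert c.positives == (df["ref"] == c.key).sum()
            assert c.n == len(df)


class TestSensSpec:
    def test_paper_overall_sensitivity_and_specificity(self):
        counts = st.ConfusionCounts("overall", "overall", tp=910, fn=155,
                                    fp=49, tn=4406)
        res = st.sens_spec(counts)
        assert round(100 * res.sensitivity, 1) == 85.4
        assert round(100 * res.specificity, 1) == 98.9

    def test_zero_positive_denominator_is_undefined(self):
        res = st.sens_spec(st.ConfusionCounts("o", "o", 0, 3, 7, 0))
        assert np.isnan(res.sensitivity)
        assert not np.isnan(res.specificity)

    def test_boundary_zero_sensitivity(self):
        res = st.sens_spec(st.ConfusionCounts("o", "o", 0, 0, 5, 10))
        assert res.sensitivity == 0.0

    def test_point_estimate_inside_wilson_interval(self):
        for x, n in [(0, 10), (5, 10), (10, 10), (910, 1065)]:
            lo, hi = st.wilson_interval(x, n)
            assert lo <= x / n <= hi


class TestWilson:
    def test_paper_sensitivity_lower_bound(self):
        lo, _ = st.wilson_interval(910, 1065)
        assert round(lo, 3) == 0.832

    def test_paper_specificity_interval(self):
        lo, hi = st.wilson_interval(4406, 4455)
        assert (round(lo, 3), round(hi, 3)) == (0.985, 0.992)

    def test_zero_successes_lower_bound_is_zero(self):
        lo, _ = st.wilson_interval(0, 10)
        assert lo == pytest.approx(0.0, abs=1e-12)

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (10 ** 3, 10 ** 6):
            lo, hi = st.wilson_interval(int(0.3 * n), n)
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 10

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            st.wilson_interval(0, 0)


class TestMcNemar:
    def test_exact_enumeration_example(self):
        # b=5, c=1: 2 * P(X <= 1 | n=6) = 2 * 7/64
        assert st.mcnemar_exact(5, 1) == pytest.approx(2 * 7 / 64)

    @pytest.mark.parametrize("b,c", [(0, 0), (3, 3), (7, 7)])
    def test_symmetric_discordance_capped_at_one(self, b, c):
        assert st.mcnemar_exact(b, c) == 1.0

    @pytest.mark.parametrize("b,c", list(itertools.product(range(0, 9),
                                                           range(0, 9))))
    def test_matches_binomial_tail_oracle(self, b, c):
        n = b + c
        if n == 0:
            expected = 1.0
        else:
            k = min(b, c)
            tail = sum(comb(n, i, exact=True) for i in range(k + 1)) / 2 ** n
            expected = min(1.0, 2 * tail)
        assert st.mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)


def fisher_enumeration_oracle(table):
    """Sum hypergeometric probabilities of all margin-consistent tables at
    most as probable as the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestFisher:
    def test_hand_computed_example(self):
        assert st.fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_zero_row_gives_p_one(self):
        assert st.fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 11, (2, 2))
        assert st.fisher_exact_2x2(table) == \
            pytest.approx(fisher_enumeration_oracle(table), abs=1e-9)


class TestCochranArmitage:
    def test_equal_proportions_give_zero_trend(self):
        z, p = st.cochran_armitage([10, 20, 30], [100, 200, 300])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_trend_is_significant(self):
        x = [10, 30, 60, 90]
        n = [100, 100, 100, 100]
        _, p = st.cochran_armitage(x, n)
        assert p < 1e-6

    def test_reversing_order_flips_sign(self):
        x, n = [5, 15, 40], [100, 100, 100]
        z1, p1 = st.cochran_armitage(x, n)
        z2, p2 = st.cochran_armitage(x[::-1], n[::-1])
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_trend_statistic_matches_direct_formula(self):
        x = np.array([8.0, 14, 25, 30])
        n = np.array([60.0, 70, 80, 90])
        s = np.array([1.0, 2, 3, 4])
        pbar = x.sum() / n.sum()
        num = np.sum(s * (x - n * pbar))
        var = pbar * (1 - pbar) * (np.sum(n * s ** 2)
                                   - np.sum(n * s) ** 2 / n.sum())
        z, _ = st.cochran_armitage(x, n)
        assert z == pytest.approx(num / np.sqrt(var), abs=1e-12)

    def test_all_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            st.cochran_armitage([0, 0], [0, 0])


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        chi2, df, p = st.chi_square_homogeneity([10, 20, 30], [50, 100, 150])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_twelve_groups_have_df_eleven(self):
        rng = np.random.default_rng(0)
        n = np.full(12, 230)
        x = rng.integers(180, 228, 12)
        _, df, _ = st.chi_square_homogeneity(x, n)
        assert df == 11

    def test_two_by_two_matches_closed_form(self):
        # closed form: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)
        a, b, c, d = 10, 40, 20, 30
        N = a + b + c + d
        expected = N * (a * d - b * c) ** 2 / \
            ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, df, _ = st.chi_square_homogeneity([a, c], [a + b, c + d])
        assert chi2 == pytest.approx(expected, abs=1e-9)
        assert df == 1

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError):
            st.chi_square_homogeneity([0, 0], [10, 20])


def patient_block(pid, n_missed=0, n_fp=0):
    rows = []
    k = 0
    for side in ("left", "right"):
        for idx in range(1, 13):
            ref, pred = "negative", "negative"
            if k < n_missed:
                ref, pred = "displaced", "negative"
            elif k < n_missed + n_fp:
                ref, pred = "negative", "old"
            rows.append({"patient": pid, "side": side, "rib_index": idx,
                         "ref": ref, "pred": pred})
            k += 1
    return rows


class TestPerPatientErrors:
    def test_perfect_predictions_all_exact(self):
        df = pd.DataFrame(sum((patient_block(f"P{i}") for i in range(5)), []))
        out = st.per_patient_error_table(df)
        assert out.loc["exact_match", "pct"] == 100.0

    def test_error_based_not_net_count_classification(self):
        """One missed plus one false positive preserves the net fracture
        count but is still a two-error patient, not an exact match."""
        df = pd.DataFrame(patient_block("P0", n_missed=1, n_fp=1))
        out = st.per_patient_error_table(df)
        assert out.loc["exact_match", "count"] == 0
        assert out.loc["other", "count"] == 1

    def test_category_counts(self):
        blocks = (patient_block("A") + patient_block("B", n_missed=1)
                  + patient_block("C", n_fp=1) + patient_block("D", n_missed=2)
                  + patient_block("E", n_fp=2) + patient_block("F", n_missed=3))
        out = st.per_patient_error_table(pd.DataFrame(blocks))
        assert out["count"].tolist() == [1, 1, 1, 1, 1, 1]
        assert out.attrs["n_patients"] == 6
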