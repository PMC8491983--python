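import numpy as np
import pandas as pd
import pytest

from pdl1quant.stats import (
    PatientRecord,
    combined_class,
    concordance,
    cox_fit,
    km_curve,
    logrank,
    pearson_r,
    positivity_rate,
    records_to_frame,
    response_table,
)


def make_calls(n_pos_pos, n_neg_neg, n_dig_only, n_phys_only):
    phys = ["positive"] * n_pos_pos + ["negative"] * n_neg_neg
    dig = ["positive"] * n_pos_pos + ["negative"] * n_neg_neg
    phys += ["negative"] * n_dig_only + ["positive"] * n_phys_only
    dig += ["positive"] * n_dig_only + ["negative"] * n_phys_only
    return phys, dig


class TestConcordance:
    def test_published_two_by_two_arithmetic(self):
        """49 both+, 50 both-, 46 digital-only, 11 physician-only out of
        156 gives 63.5% agreement and 38.5% / 60.9% positivity rates."""
        phys, dig = make_calls(49, 50, 46, 11)
        table = concordance(phys, dig)
        assert table.n_total == 156
        assert table.percent_agreement == 63.5
        assert table.percent_discordance == 36.5
        assert positivity_rate(phys) == 38.5
        assert positivity_rate(dig) == 60.9

    def test_identical_and_complementary_vectors(self):
        calls = ["positive", "negative", "positive"]
        assert concordance(calls, calls).percent_agreement == 100.0
        flipped = ["negative", "positive", "negative"]
        assert concordance(calls, flipped).percent_agreement == 0.0

    def test_agreement_plus_discordance_is_exactly_100(self, rng):
        for _ in range(20):
            calls_a = rng.random(rng.integers(3, 50)) > rng.random()
            calls_b = rng.random(calls_a.size) > rng.random()
            t = concordance(calls_a.tolist(), calls_b.tolist())
            assert t.percent_agreement + t.percent_discordance == 100.0

    def test_length_mismatch_and_missing_rejected(self):
        with pytest.raises(ValueError):
            concordance(["positive"], ["positive", "negative"])
        with pytest.raises(ValueError):
            concordance(["positive", None], ["positive", "negative"])

    def test_empty_positivity_rejected(self):
        with pytest.raises(ValueError):
            positivity_rate([])


class TestCombinedClass:
    @pytest.mark.parametrize(
        "phys, dig, expected",
        [
            ("positive", "positive", "both_positive"),
            ("negative", "negative", "both_negative"),
            ("positive", "negative", "single_positive"),
            ("negative", "positive", "single_positive"),
        ],
    )
    def test_three_level_mapping(self, phys, dig, expected):
        assert combined_class(phys, dig) == expected

    def test_missing_call_rejected(self):
        with pytest.raises(ValueError):
            combined_class(None, "positive")


def make_bor_records(spec):
    """spec: list of (group_label, n_responders, n_total)."""
    recs = []
    i = 0
    for g, k, n in spec:
        for j in range(n):
            recs.append(
                PatientRecord(
                    id=f"r{i}",
                    physician_call="positive" if g == "A" else "negative",
                    digital_call="positive" if g == "A" else "negative",
                    bor_responder=j < k,
                )
            )
            i += 1
    return recs


class TestResponseTable:
    def test_two_group_chi_square_hand_value(self):
        # O = [[30,30],[20,40]] -> E = [[25,35],[25,35]],
        # chi2 = 1 + 25/35 + 1 + 25/35 = 3.4286
        recs = make_bor_records([("A", 30, 60), ("B", 20, 60)])
        rt = response_table(recs, lambda r: "A" if r.physician_call == "positive" else "B")
        assert rt.df == 1
        assert rt.chi_square == pytest.approx(24.0 / 7.0, abs=1e-6)

    def test_identical_rates_give_zero_statistic(self):
        recs = make_bor_records([("A", 15, 60), ("B", 15, 60)])
        rt = response_table(recs, lambda r: r.physician_call)
        assert rt.chi_square == pytest.approx(0.0, abs=1e-12)
        assert rt.p_value == pytest.approx(1.0)

    def test_three_groups_have_two_degrees_of_freedom(self):
        recs = make_bor_records([("A", 10, 30), ("B", 12, 30)])
        rt = response_table(
            recs, lambda r: {0: "x", 1: "y", 2: "z"}[int(r.id[1:]) % 3]
        )
        assert rt.df == 2

    def test_zero_expected_cell_rejected(self):
        recs = make_bor_records([("A", 0, 20), ("B", 0, 20)])
        with pytest.raises(ValueError, match="chi-square"):
            response_table(recs, lambda r: r.physician_call)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        r, _ = pearson_r(x, x)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # r = 5 / sqrt(2 * 38/3) = 0.99339
        r, p = pearson_r([1, 2, 3], [2, 4, 7])
        assert r == pytest.approx(5.0 / np.sqrt(2.0 * 38.0 / 3.0), abs=1e-9)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [2, 4, 7])


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        # events at 1, 3, 4; censored at 2: S = 0.75, 0.375, 0; median 3
        curve = km_curve([1, 2, 3, 4], [True, False, True, True])
        np.testing.assert_array_equal(curve.event_times, [1, 3, 4])
        np.testing.assert_allclose(curve.survival_probs, [0.75, 0.375, 0.0])
        np.testing.assert_array_equal(curve.n_at_risk, [4, 2, 1])
        assert curve.median == 3

    def test_all_censored_median_not_reached(self):
        curve = km_curve([5, 7, 9], [False, False, False])
        assert curve.median is None
        assert curve.event_times.size == 0

    def test_single_event(self):
        curve = km_curve([5], [True])
        assert curve.survival_probs[-1] == 0.0 and curve.median == 5

    def test_uncensored_data_matches_empirical_survival(self, rng):
        t = rng.exponential(10, 200)
        curve = km_curve(t, np.ones(200, bool))
        for ti, si in zip(curve.event_times, curve.survival_probs):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [True] * 5
        stat, p = logrank([(t, e), (t, e)])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        g1 = (rng.exponential(5, 60), rng.random(60) < 0.8)
        g2 = (rng.exponential(12, 60), rng.random(60) < 0.8)
        stat_a, p_a = logrank([g1, g2])
        stat_b, p_b = logrank([g2, g1])
        assert stat_a == pytest.approx(stat_b)
        assert p_a == pytest.approx(p_b)

    def test_separated_groups_significant(self, rng):
        t1 = rng.exponential(5, 200)
        t2 = rng.exponential(10, 200)
        stat, p = logrank([(t1, np.ones(200, bool)), (t2, np.ones(200, bool))])
        assert p < 0.05

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            logrank([([1, 2], [False, False]), ([3], [False])])


def simulate_cox_records(n, hr, rng, base_median=10.0, censor=30.0):
    x = rng.random(n) < 0.5
    rate = np.log(2) / base_median * np.where(x, hr, 1.0)
    t = rng.exponential(1.0 / rate)
    c = rng.uniform(0, censor, n)
    return pd.DataFrame(
        {
            "pfs_months": np.minimum(t, c),
            "pfs_event": t <= c,
            "x": x.astype(float),
        }
    )


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(7)
        df = simulate_cox_records(500, 0.5, rng)
        fit = cox_fit(df, "pfs", ["x"])
        assert 0.40 <= fit.hazard_ratio("x") <= 0.62
        lo, hi = fit.ci("x")
        assert lo < fit.hazard_ratio("x") < hi
        assert fit.ties_method == "efron"

    def test_bias_small_at_large_n(self):
        """The HR estimate converges to the generating rate ratio: the
        mean log-HR over replicates at n=5000 is within 5% of truth."""
        rng = np.random.default_rng(2718)
        log_hrs = []
        for _ in range(8):
            df = simulate_cox_records(5000, 0.5, rng)
            log_hrs.append(np.log(cox_fit(df, "pfs", ["x"]).hazard_ratio("x")))
        hr = np.exp(np.mean(log_hrs))
        assert abs(hr - 0.5) / 0.5 < 0.05

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(999)
        hits = 0
        for _ in range(100):
            df = simulate_cox_records(1000, 1.0, rng)
            lo, hi = cox_fit(df, "pfs", ["x"]).ci("x")
            hits += int(lo <= 1.0 <= hi)
        assert hits >= 90

    def test_constant_covariate_named_in_error(self):
        rng = np.random.default_rng(5)
        df = simulate_cox_records(100, 1.0, rng)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, "pfs", ["flat"])

    def test_complete_case_exclusions_counted(self):
        rng = np.random.default_rng(6)
        df = simulate_cox_records(100, 1.0, rng)
        df.loc[:9, "x"] = np.nan
        fit = cox_fit(df, "pfs", ["x"])
        assert fit.n_excluded == 10 and fit.n_used == 90

    def test_records_interface(self):
        recs = [
            PatientRecord(
                id=f"p{i}",
                physician_call="positive",
                digital_call="positive" if i % 2 else "negative",
                pfs_months=float(i + 1),
                os_months=float(i + 2),
                pfs_event=True,
                os_event=(i % 3 == 0),
                age_gt65=bool(i % 2),
            )
            for i in range(40)
        ]
        fit = cox_fit(recs, "os", ["age_gt65"])
        assert fit.n_used == 40
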