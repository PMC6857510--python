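import numpy as np
import pandas as pd
import pytest

import ehrphen as e
from ehrphen.errors import (
    DegenerateInputError,
    InvalidArgumentError,
    NoDataError,
)
from ehrphen.validation import (
    ContingencyTable,
    cox_fit,
    cross_source_concordance,
    diagnostic_accuracy,
    external_population_run,
    genetic_replication,
    km_curve,
)


# ---------------------------------------------------------------------------
# cross-source concordance
# ---------------------------------------------------------------------------

def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "source", "date"])


class TestConcordance:
    def test_percentages_match_printed_count_arithmetic(self):
        """Pattern summarization turns counts into 1-decimal percentages:
        with 17,964 cases, 5,561 in all three sources is 31.0%."""
        rows = []
        for i in range(5561):
            for src in ("primary", "hospital", "registry"):
                rows.append((f"t{i}", src, "2004-01-01"))
        for i in range(17964 - 5561):
            rows.append((f"s{i}", "primary", "2004-01-01"))
        res = cross_source_concordance(_events(rows))
        assert res.total == 17964
        assert res.pattern_percentages["primary+hospital+registry"] == 31.0
        assert res.percentage(13380) == 74.5
        assert res.percentage(9438) == 52.5
        assert res.percentage(11482) == 63.9

    def test_single_source_cases_have_zero_multisource_percentage(self):
        rows = [(f"p{i}", "hospital", "2004-01-01") for i in range(50)]
        res = cross_source_concordance(_events(rows))
        assert res.k_or_more_percentages[2] == 0.0
        assert res.k_or_more_percentages[1] == 100.0

    def test_pattern_counts_partition_the_case_set(self, rng):
        rows = []
        for i in range(300):
            for src in rng.choice(
                ["primary", "hospital", "registry", "death"],
                size=rng.integers(1, 4), replace=False,
            ):
                rows.append((f"p{i}", src, "2004-01-01"))
        res = cross_source_concordance(_events(rows))
        assert sum(res.pattern_counts.values()) == res.total == 300

    def test_windowed_patterns_match_brute_force_pairwise_check(self, rng):
        """500 synthetic cases with known offsets: the 30-day-window pattern
        equals a brute-force earliest-record/date-difference scan."""
        anchor = pd.Timestamp("2004-06-01")
        rows = []
        per_patient = {}
        for i in range(500):
            pid = f"p{i}"
            srcs = rng.choice(
                ["primary", "hospital", "registry", "death"],
                size=rng.integers(1, 5), replace=False,
            )
            dates = {}
            for s in srcs:
                d = anchor + pd.Timedelta(days=int(rng.integers(-60, 61)))
                dates[s] = d
                rows.append((pid, s, d.strftime("%Y-%m-%d")))
            per_patient[pid] = dates
        res = cross_source_concordance(_events(rows), window_days=30)
        oracle = {}
        for pid, dates in per_patient.items():
            earliest = min(dates.values())
            pat = "+".join(
                s
                for s in ("primary", "hospital", "registry", "death")
                if s in dates and (dates[s] - earliest).days <= 30
            )
            oracle[pat] = oracle.get(pat, 0) + 1
        assert res.pattern_counts == oracle

    def test_infinite_window_equals_set_union(self, rng):
        rows = []
        union = {}
        for i in range(200):
            pid = f"p{i}"
            srcs = set(
                rng.choice(
                    ["primary", "hospital", "death"],
                    size=rng.integers(1, 4), replace=False,
                )
            )
            union[pid] = srcs
            for s in srcs:
                rows.append(
                    (pid, s, f"200{rng.integers(0, 9)}-06-01")
                )
        res = cross_source_concordance(_events(rows), window_days=np.inf)
        oracle = {}
        for pid, srcs in union.items():
            pat = "+".join(
                s for s in ("primary", "hospital", "registry", "death") if s in srcs
            )
            oracle[pat] = oracle.get(pat, 0) + 1
        assert res.pattern_counts == oracle

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(NoDataError):
            cross_source_concordance(_events([]))
        with pytest.raises(InvalidArgumentError):
            cross_source_concordance(
                _events([("p", "primary", "2004-01-01")]), window_days=-5
            )


# ---------------------------------------------------------------------------
# diagnostic accuracy
# ---------------------------------------------------------------------------

class TestDiagnosticAccuracy:
    def test_registry_comparison_ppv_with_wilson_ci(self):
        """PPV 6660/7224 = 92.2% (95% CI 91.6-92.8) and 6851/7489 = 91.5%
        (90.8-92.1) at one-decimal percent rounding."""
        rep = diagnostic_accuracy(ContingencyTable(tp=6660, fp=564, fn=0, tn=0))
        assert rep.ppv.percent() == (92.2, 91.6, 92.8)
        rep2 = diagnostic_accuracy(ContingencyTable(tp=6851, fp=638, fn=0, tn=0))
        assert rep2.ppv.percent() == (91.5, 90.8, 92.1)

    def test_perfect_table_all_metrics_one(self):
        rep = diagnostic_accuracy(ContingencyTable(tp=10, fp=0, fn=0, tn=10))
        for name in ("ppv", "npv", "sensitivity", "specificity"):
            assert getattr(rep, name).estimate == 1.0
            assert getattr(rep, name).ci_high <= 1.0

    def test_zero_denominator_reported_absent_with_reason(self):
        rep = diagnostic_accuracy(ContingencyTable(tp=5, fp=2, fn=0, tn=0))
        assert rep.npv.estimate is None
        assert rep.npv.reason == "zero denominator"

    def test_swapping_tp_tn_and_fp_fn_swaps_metric_pairs(self, rng):
        tp, fp, fn, tn = rng.integers(1, 500, 4)
        a = diagnostic_accuracy(ContingencyTable(tp, fp, fn, tn))
        b = diagnostic_accuracy(ContingencyTable(tn, fn, fp, tp))
        assert a.sensitivity.estimate == pytest.approx(b.specificity.estimate)
        assert a.specificity.estimate == pytest.approx(b.sensitivity.estimate)
        assert a.ppv.estimate == pytest.approx(b.npv.estimate)
        assert a.npv.estimate == pytest.approx(b.ppv.estimate)

    def test_wald_available(self):
        rep = diagnostic_accuracy(
            ContingencyTable(tp=6660, fp=564, fn=0, tn=0), ci_method="wald"
        )
        assert rep.ppv.percent() == (92.2, 91.6, 92.8)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def km_oracle(durations, events):
    """Independent product over risk sets: S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    times = np.unique(durations[events])
    surv = []
    s = 1.0
    for t in times:
        n_at_risk = (durations >= t).sum()
        d = ((durations == t) & events).sum()
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return times, np.array(surv)


class TestKaplanMeier:
    def test_no_events_survival_identically_one(self):
        curve = km_curve([5, 6, 7], [False, False, False])
        assert curve.survival_at(100) == 1.0
        assert curve.event_times.size == 0

    def test_three_events_product_limit_by_hand(self):
        curve = km_curve([1, 2, 3], [True, True, True])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(curve.cumulative_incidence, [1 / 3, 2 / 3, 1.0])

    def test_curve_monotone_nonincreasing_from_one(self, rng):
        t = rng.exponential(10, 100)
        ev = rng.random(100) < 0.7
        curve = km_curve(t, ev)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival[0] <= 1.0

    def test_matches_risk_set_product_oracle_pointwise(self, rng):
        t = np.minimum(rng.exponential(10, 200), rng.exponential(15, 200))
        censor = rng.exponential(12, 200)
        obs = np.minimum(t, censor)
        ev = t <= censor
        curve = km_curve(obs, ev)
        times, surv = km_oracle(obs, ev)
        assert np.allclose(curve.event_times, times)
        assert np.allclose(curve.survival, surv, atol=1e-10)

    def test_no_censoring_final_value_is_empirical_fraction(self, rng):
        t = rng.exponential(5, 150)
        curve = km_curve(t, np.ones(150, bool))
        assert curve.survival[-1] == pytest.approx(0.0, abs=1e-12)
        mid = np.median(t)
        assert curve.survival_at(mid) == pytest.approx((t > mid).mean(), abs=1 / 150)

    def test_degenerate_all_censored_at_zero(self):
        with pytest.raises(DegenerateInputError):
            km_curve([0, 0, 0], [False, False, False])


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def breslow_neg_log_partial_likelihood(beta, durations, events, x):
    """Hand-rolled Breslow log partial likelihood for one covariate."""
    order = np.argsort(durations)
    t, ev, xv = durations[order], events[order], x[order]
    ll = 0.0
    for ti in np.unique(t[ev]):
        at_risk = t >= ti
        d = ev & (t == ti)
        ll += beta * xv[d].sum() - d.sum() * np.log(
            np.exp(beta * xv[at_risk]).sum()
        )
    return -ll


class TestCox:
    def test_two_identical_groups_hr_one(self):
        t = np.tile([2.0, 4.0, 6.0, 8.0, 10.0], 2)
        ev = np.tile([1, 1, 0, 1, 1], 2)
        x = np.repeat([0.0, 1.0], 5)
        fit = cox_fit(t, ev, pd.DataFrame({"g": x}))
        assert fit.hazard_ratios["g"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_of_partial_likelihood(self, rng):
        """On 10 subjects the Newton solution coincides with brute-force grid
        maximization of the hand-written Breslow partial likelihood."""
        t = rng.exponential(5, 10)
        ev = rng.random(10) < 0.8
        ev[0] = True
        x = (rng.random(10) < 0.5).astype(float)
        fit = cox_fit(t, ev, pd.DataFrame({"x": x}))
        grid = np.arange(-3, 3, 0.001)
        nll = [breslow_neg_log_partial_likelihood(b, t, ev, x) for b in grid]
        oracle = grid[int(np.argmin(nll))]
        assert fit.coefficients["x"] == pytest.approx(oracle, abs=0.005)

    def test_nominal_ci_coverage_for_true_hr_two(self):
        rng = np.random.default_rng(99)
        true_beta = np.log(2.0)
        covered = 0
        reps = 40
        for _ in range(reps):
            n = 400
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1.0 / np.exp(true_beta * x))
            censor = rng.exponential(1.5, n)
            obs = np.minimum(t, censor)
            ev = t <= censor
            fit = cox_fit(obs, ev, pd.DataFrame({"x": x}))
            if fit.hr_ci_low["x"] <= 2.0 <= fit.hr_ci_high["x"]:
                covered += 1
        assert covered >= 34  # ~nominal 95% of 40, allowing binomial noise

    def test_null_covariate_rarely_significant(self):
        rng = np.random.default_rng(7)
        ok = 0
        reps = 100
        for _ in range(reps):
            n = 150
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1.0, n)
            censor = rng.exponential(1.5, n)
            obs = np.minimum(t, censor)
            ev = t <= censor
            fit = cox_fit(obs, ev, pd.DataFrame({"x": x}))
            if abs(fit.coefficients["x"]) < 3 * fit.standard_errors["x"]:
                ok += 1
        assert ok >= 97

    def test_no_events_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cox_fit([1, 2, 3], [0, 0, 0], pd.DataFrame({"x": [0.0, 1.0, 0.0]}))

    def test_rank_deficient_covariates_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(InvalidArgumentError):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 0], df)


# ---------------------------------------------------------------------------
# genetic replication
# ---------------------------------------------------------------------------

class TestReplication:
    def test_bonferroni_threshold_for_31_variants(self):
        res = genetic_replication(
            pd.DataFrame(
                {
                    "effect_discovery": np.ones(31),
                    "effect_replication": np.ones(31),
                    "p_replication": np.full(31, 0.5),
                }
            ),
            alpha=0.05,
        )
        assert res.bonferroni_threshold == pytest.approx(0.05 / 31)
        assert round(res.bonferroni_threshold, 4) == 0.0016

    def test_strong_concordant_variant_replicates(self):
        res = genetic_replication(
            pd.DataFrame(
                {
                    "effect_discovery": [0.3],
                    "effect_replication": [0.1],
                    "p_replication": [1e-6],
                }
            )
        )
        assert res.n_bonferroni_replicated == 1

    def test_discordant_direction_never_replicates(self):
        res = genetic_replication(
            pd.DataFrame(
                {
                    "effect_discovery": [0.3],
                    "effect_replication": [-0.4],
                    "p_replication": [1e-10],
                }
            )
        )
        assert res.n_bonferroni_replicated == 0
        assert res.n_nominal_concordant == 0

    def test_zero_effect_flagged_not_counted(self):
        res = genetic_replication(
            pd.DataFrame(
                {
                    "effect_discovery": [0.0],
                    "effect_replication": [0.5],
                    "p_replication": [1e-10],
                }
            )
        )
        assert res.n_direction_undefined == 1
        assert res.n_bonferroni_replicated == 0

    def test_random_table_matches_elementwise_classification(self, rng):
        m = 100
        df = pd.DataFrame(
            {
                "effect_discovery": rng.normal(0, 1, m),
                "effect_replication": rng.normal(0, 1, m),
                "p_replication": rng.random(m),
            }
        )
        alpha = 0.05
        res = genetic_replication(df, alpha=alpha)
        thr = alpha / m
        nominal = bonf = 0
        for _, row in df.iterrows():
            concord = np.sign(row.effect_discovery) == np.sign(row.effect_replication)
            if concord and row.p_replication < alpha:
                nominal += 1
            if concord and row.p_replication < thr:
                bonf += 1
        assert res.n_nominal_concordant == nominal
        assert res.n_bonferroni_replicated == bonf
        assert res.n_bonferroni_replicated <= res.n_nominal_concordant <= m


# ---------------------------------------------------------------------------
# external populations
# ---------------------------------------------------------------------------

class TestExternalPopulations:
    def _config(self, patterns, seed=31):
        return e.GeneratorConfig(
            n_patients=3000,
            seed=seed,
            phenotype=e.PhenotypeSpec(case_probability=0.4, pattern_probs=patterns),
        )

    def test_identical_configs_identical_reports(self, toy_def):
        patterns = {"primary": 0.5, "hospital": 0.5}
        cmp = external_population_run(
            self._config(patterns), self._config(patterns), toy_def
        )
        a, b = cmp.to_frame().iloc[0], cmp.to_frame().iloc[1]
        assert a.drop("cohort").equals(b.drop("cohort"))
        assert "population A" in cmp.summary_text()
        assert "population B" in cmp.summary_text()

    def test_pattern_shift_changes_concordance_but_not_accuracy(self, toy_def):
        cmp = external_population_run(
            self._config({"primary": 0.7, "hospital": 0.3}),
            self._config({"primary": 0.3, "hospital": 0.7}),
            toy_def,
        )
        ca = cmp.report_a.concordance.pattern_percentages
        cb = cmp.report_b.concordance.pattern_percentages
        assert ca != cb
        assert cmp.report_a.accuracy.ppv.estimate == cmp.report_b.accuracy.ppv.estimate
        assert (
            cmp.report_a.accuracy.sensitivity.estimate
            == cmp.report_b.accuracy.sensitivity.estimate
        )

    def test_mismatched_definitions_rejected(self, toy_def):
        other = e.toy_definition("atrial fibrillation")
        with pytest.raises(InvalidArgumentError):
            external_population_run(
                self._config({"primary": 1.0}),
                self._config({"primary": 1.0}),
                toy_def,
                other,
            )
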