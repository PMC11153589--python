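"""Benchmarking: labels, metrics vs brute-force oracles, bootstrap, survival."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

import clltim as ct
from clltim.ensemble import Prediction
from clltim.evaluation import (
    BootstrapConfig,
    ComparatorScore,
    ConfusionMatrix,
    bootstrap_summary,
    classification_metrics,
    label_outcomes,
    missingness_vs_correctness,
    pr_auc,
    profile_missingness,
    survival_benchmark,
)
from clltim.features import PredictionPointPolicy
from clltim.synth import UNKNOWN, ConfigurationError, PatientRecord

from conftest import small_spec


def patient(pid="P0", diag=1000, outcome=("none", None), fu_end=4000,
            baseline=None, labs=(), cultures=()):
    return PatientRecord(
        patient_id=pid, diagnosis_day=diag, baseline=baseline or {},
        lab_events=list(labs), culture_events=list(cultures),
        outcome_type=outcome[0], outcome_day=outcome[1],
        followup_end_day=fu_end,
    )


PP = 1092  # diagnosis 1000 + 92


class TestLabelOutcomes:
    def test_event_within_horizon_is_positive(self):
        [lab] = label_outcomes([patient(outcome=("infection", PP + 100))])
        assert lab.label == "positive" and lab.event and lab.time_days == 100

    def test_short_followup_without_event_is_excluded_but_censored(self):
        [lab] = label_outcomes([patient(fu_end=PP + 400)])
        assert lab.label == "excluded"
        assert lab.time_days == 400 and not lab.event

    def test_followup_just_past_horizon_is_negative(self):
        [lab] = label_outcomes([patient(fu_end=PP + 731)])
        assert lab.label == "negative" and not lab.event

    def test_event_beyond_horizon_is_negative_for_classification(self):
        [lab] = label_outcomes([patient(outcome=("treatment", PP + 800),
                                        fu_end=PP + 900)])
        assert lab.label == "negative" and lab.event and lab.time_days == 800

    def test_event_before_prediction_point_is_flagged(self):
        [lab] = label_outcomes([patient(outcome=("treatment", 1050))])
        assert lab.label == "excluded"
        assert lab.reason == "event_before_prediction_point"


class TestClassificationMetrics:
    def test_printed_confusion_matrix_reproduces_reported_metrics(self):
        """The research-cohort benchmark matrix (43, 17, 71, 14)."""
        m = classification_metrics(ConfusionMatrix(43, 17, 71, 14))
        assert m["recall"] == pytest.approx(0.754, abs=5e-4)
        assert m["precision"] == pytest.approx(43 / 60, abs=1e-12)
        assert m["MCC"] == pytest.approx(0.557, abs=5e-4)

    def test_perfect_predictions(self):
        m = classification_metrics(ConfusionMatrix(10, 0, 20, 0))
        assert m["MCC"] == 1.0 and m["precision"] == 1.0 and m["recall"] == 1.0

    def test_undefined_denominators_reported_as_none(self):
        m = classification_metrics(ConfusionMatrix(0, 0, 5, 5))
        assert m["precision"] is None and m["MCC"] is None

    def test_agreement_with_brute_force_oracle_on_random_matrices(self):
        """1000 random confusion matrices vs sklearn recomputed from the
        expanded label vectors, to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 40, size=4)
            if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
                continue
            y = np.concatenate([np.ones(tp + fn), np.zeros(tn + fp)])
            yhat = np.concatenate(
                [np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)]
            )
            m = classification_metrics(ConfusionMatrix(tp, fp, tn, fn))
            assert m["MCC"] == pytest.approx(matthews_corrcoef(y, yhat),
                                             abs=1e-12)
            assert m["precision"] == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert m["recall"] == pytest.approx(tp / (tp + fn), abs=1e-12)


def brute_force_ap(scores, y):
    """Exhaustive-threshold step-wise PR area: sum (R_i - R_{i-1}) * P_i."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(y)[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    precision = tps / (tps + fps)
    recall = tps / y.sum()
    # collapse tied scores to their last cumulative point
    s = np.asarray(scores)[order]
    last_of_threshold = np.r_[s[1:] != s[:-1], True]
    p, r = precision[last_of_threshold], recall[last_of_threshold]
    r_prev = np.r_[0.0, r[:-1]]
    return float(np.sum((r - r_prev) * p))


class TestPRAUC:
    def test_perfect_separation_gives_one(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        assert pr_auc([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_single_class_undefined(self):
        assert pr_auc([0.2, 0.4], [1, 1]) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_toy_scores_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=6)
        y = rng.integers(0, 2, size=6)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        assert pr_auc(scores, y) == pytest.approx(brute_force_ap(scores, y),
                                                  abs=1e-12)


class TestBootstrap:
    def test_identical_patients_give_zero_width_ci(self):
        df = pd.DataFrame({"y": [1.0] * 20, "stratum": ["a"] * 20})
        out = bootstrap_summary(df, lambda d: d["y"].mean(),
                                BootstrapConfig(replicates=200, seed=0))
        assert out["ci_low"] == out["ci_high"] == out["mean"] == 1.0

    def test_default_replicates_is_5000(self):
        assert BootstrapConfig().replicates == 5000

    def test_empty_stratum_errors(self):
        df = pd.DataFrame({"y": [1.0, 0.0], "stratum": ["a", "b"]})
        with pytest.raises(ConfigurationError):
            bootstrap_summary(df, lambda d: d["y"].mean(),
                              BootstrapConfig(replicates=10, seed=0))

    def test_stratified_resampling_preserves_stratum_sizes(self):
        df = pd.DataFrame({
            "y": np.r_[np.ones(30), np.zeros(10)],
            "stratum": ["hi"] * 30 + ["lo"] * 10,
        })
        # the fraction of 'hi' patients is invariant under stratification
        out = bootstrap_summary(
            df, lambda d: (d["stratum"] == "hi").mean(),
            BootstrapConfig(replicates=100, seed=1),
        )
        assert out["mean"] == 0.75 and out["ci_low"] == out["ci_high"] == 0.75

    def test_mean_converges_to_point_estimate_for_linear_statistic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.random(100), "stratum": ["a"] * 100})
        out = bootstrap_summary(df, lambda d: d["y"].mean(),
                                BootstrapConfig(replicates=50_000, seed=3))
        assert out["mean"] == pytest.approx(df["y"].mean(), abs=0.002)

    def test_percentile_ci_covers_truth_at_nominal_rate(self):
        """Binomial proportion, n = 200, p = 0.3: the 95% percentile
        bootstrap CI covers the truth in ~95% of simulations (+- 2%)."""
        rng = np.random.default_rng(4)
        n, p, sims, reps = 200, 0.3, 1000, 400
        covered = 0
        for _ in range(sims):
            y = rng.random(n) < p
            phat = y.mean()
            # resampling a proportion with replacement == binomial draw
            boots = rng.binomial(n, phat, size=reps) / n
            lo, hi = np.percentile(boots, [2.5, 97.5])
            covered += lo <= p <= hi
        assert abs(covered / sims - 0.95) < 0.02


def _preds_and_labels(n=200, seed=0, hr=3.0):
    """Synthetic exponential survival with a known high/low risk split."""
    rng = np.random.default_rng(seed)
    high = rng.random(n) < 0.5
    rate = np.where(high, hr * 0.0005, 0.0005)
    t_event = rng.exponential(1 / rate)
    t_cens = rng.uniform(200, 1500, n)
    preds, labels = [], []
    for i in range(n):
        t = min(t_event[i], t_cens[i])
        event = t_event[i] <= t_cens[i]
        label = (
            "positive" if event and t <= 730
            else ("negative" if t >= 730 else "excluded")
        )
        labels.append(ct.OutcomeLabel(f"P{i}", label, int(t), bool(event)))
        preds.append(Prediction(f"P{i}", 0.8 if high[i] else 0.2,
                                "high" if high[i] else "low",
                                "high_conf_high_risk" if high[i]
                                else "high_conf_low_risk"))
    return preds, labels


class TestSurvival:
    def test_identical_groups_give_unit_hazard_ratio(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(800, 40).astype(int) + 1
        events = rng.random(40) < 0.7
        preds, labels = [], []
        for grp, call in ((0, "low"), (1, "high")):
            for i, (t, e) in enumerate(zip(times, events)):
                pid = f"P{grp}_{i}"
                preds.append(Prediction(pid, 0.5, call, "low_confidence"))
                labels.append(ct.OutcomeLabel(pid, "negative", int(t), bool(e)))
        out = survival_benchmark(preds, labels)
        assert out["hazard_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert out["logrank_p"] == pytest.approx(1.0, abs=1e-6)

    def test_km_without_censoring_equals_empirical_survival(self):
        times = [100, 200, 300, 400]
        preds = [Prediction(f"P{i}", 0.9, "high", "high_conf_high_risk")
                 for i in range(4)]
        labels = [ct.OutcomeLabel(f"P{i}", "positive", t, True)
                  for i, t in enumerate(times)]
        out = survival_benchmark(preds, labels)
        curve = out["km_curves"]["high_risk"].set_index("time")["survival"]
        for k, t in enumerate(times):
            assert curve.loc[t] == pytest.approx(1 - (k + 1) / 4)

    def test_known_risk_split_detected(self):
        preds, labels = _preds_and_labels(n=400, seed=2, hr=3.0)
        out = survival_benchmark(preds, labels)
        assert out["hazard_ratio"] > 1.5
        assert out["logrank_p"] < 0.01

    def test_no_events_reported_not_raised(self):
        preds = [Prediction("P0", 0.6, "high", "low_confidence")]
        labels = [ct.OutcomeLabel("P0", "negative", 800, False)]
        assert survival_benchmark(preds, labels)["hazard_ratio"] is None

    def test_excluded_patients_enter_survival_censored(self):
        """The classification-excluded short-follow-up patient appears in the
        risk-group KM fit as a censored observation."""
        preds = [Prediction("P0", 0.9, "high", "high_conf_high_risk"),
                 Prediction("P1", 0.9, "high", "high_conf_high_risk")]
        labels = [ct.OutcomeLabel("P0", "positive", 300, True),
                  ct.OutcomeLabel("P1", "excluded", 400, False,
                                  reason="followup_shorter_than_horizon")]
        out = survival_benchmark(preds, labels)
        assert out["n"] == 2  # excluded patient included, censored


class TestProfileMissingness:
    def test_hand_built_depth_oracle(self):
        pp = 1092
        cohort = [
            patient("P0", labs=[("hb", pp - 730, 5.0, "u"),
                                ("hb", pp - 100, 5.0, "u"),
                                ("crp", pp - 365, 1.0, "u")]),
            patient("P1", labs=[("hb", pp - 1461, 5.0, "u")]),
            patient("P2", labs=[]),
        ]
        out = profile_missingness(cohort, ["hb", "crp"])
        # hb: earliest 730d (P0) and 1461d (P1) -> mean 1095.5d = 2.999 y
        # crp: 365d (P0) -> 0.999 y; mean over labs ~ 1.9995 y
        hb_y = (730 / 365.25 + 1461 / 365.25) / 2
        crp_y = 365 / 365.25
        assert out["historical_depth_years"] == pytest.approx((hb_y + crp_y) / 2)
        assert out["lab_availability"] == pytest.approx((1.0 + 0.5 + 0.0) / 3)

    def test_fully_observed_cohort_has_zero_baseline_missingness(self):
        cohort = [patient("P0", baseline={"binet": "A", "ighv": "mutated"})]
        out = profile_missingness(cohort, ["hb"])
        assert all(v == 0.0 for v in out["baseline_missingness"].values())

    def test_deployment_preset_binet_missingness(self):
        cohort = ct.generate_cohort(
            small_spec(seed=31, n=4000, preset="deployment")
        )
        out = profile_missingness(cohort, ["hemoglobin"])
        assert out["baseline_missingness"]["binet"] == pytest.approx(0.722,
                                                                     abs=0.025)


class TestMissingnessVsCorrectness:
    def _make(self, rates_by_group, seed=0):
        rng = np.random.default_rng(seed)
        preds, labels, rates = [], [], {}
        i = 0
        for grp, (call, truth, mu, n) in rates_by_group.items():
            for _ in range(n):
                pid = f"P{i}"; i += 1
                preds.append(Prediction(pid, 0.5, call, "low_confidence"))
                labels.append(ct.OutcomeLabel(pid, truth, 100, truth == "positive"))
                rates[pid] = float(np.clip(rng.normal(mu, 0.05), 0, 1))
        return preds, labels, pd.Series(rates)

    def test_identical_distributions_not_flagged(self):
        preds, labels, rates = self._make({
            "tp": ("high", "positive", 0.3, 40),
            "fp": ("high", "negative", 0.3, 40),
        })
        out = missingness_vs_correctness(preds, labels, rates)
        assert out["TP_vs_FP"]["p"] > 0.05

    def test_concentrated_missingness_detected(self):
        preds, labels, rates = self._make({
            "tp": ("high", "positive", 0.7, 40),
            "fp": ("high", "negative", 0.2, 40),
        })
        out = missingness_vs_correctness(preds, labels, rates)
        assert out["TP_vs_FP"]["p"] < 0.001

    def test_mcar_null_rarely_significant_across_seeds(self):
        hits = 0
        for seed in range(20):
            preds, labels, rates = self._make({
                "tp": ("high", "positive", 0.4, 30),
                "fp": ("high", "negative", 0.4, 30),
            }, seed=seed)
            out = missingness_vs_correctness(preds, labels, rates)
            hits += out["TP_vs_FP"]["p"] < 0.05
        assert hits <= 2  # >= 90% of seeds show no difference

    def test_empty_group_skipped_with_notice(self):
        preds, labels, rates = self._make({"tp": ("high", "positive", 0.3, 10)})
        out = missingness_vs_correctness(preds, labels, rates)
        assert "note" in out["TP_vs_FP"]


class TestComparator:
    def test_fully_observed_patient_scores(self):
        comp = ComparatorScore()
        baseline = {"age": "ge65", "binet": "C", "b2m": "gt4",
                    "ighv": "unmutated", "fish": "del17p"}
        points, category = comp.score(baseline)
        assert points == 1 + 1 + 2 + 2 + 4 == 10
        assert category == "very_high"
        assert comp.score({"age": "lt65", "binet": "A", "b2m": "le4",
                           "ighv": "mutated", "fish": "normal"}) == (0, "low")

    def test_complete_case_refuses_missing_inputs(self):
        comp = ComparatorScore()
        assert comp.score({"age": "ge65", "binet": UNKNOWN, "b2m": "le4",
                           "ighv": "mutated", "fish": "normal"}) is None

    def test_impute_mode_requires_only_three_inputs(self):
        comp = ComparatorScore(mode="impute_binet_ighv")
        points, _ = comp.score({"age": "ge65", "binet": UNKNOWN, "b2m": "gt4",
                                "ighv": UNKNOWN, "fish": "normal"})
        assert points == 1 + 2  # imputed Binet A / IGHV mutated add nothing

    def test_coverage_matches_brute_force_joint_availability(self):
        cohort = ct.generate_cohort(
            small_spec(seed=33, n=500, preset="deployment")
        )
        out = ct.coverage_comparison(cohort, None, ComparatorScore())
        need = ["age", "binet", "b2m", "ighv", "fish"]
        brute = np.mean([
            all(r.baseline.get(v, UNKNOWN) != UNKNOWN for v in need)
            for r in cohort
        ])
        assert out["comparator_coverage_complete_case"] == pytest.approx(brute)

    def test_coverage_monotone_in_marginal_missingness(self):
        base = ct.generate_cohort(small_spec(seed=34, n=400))
        comp = ComparatorScore()
        cov_prev = ct.coverage_comparison(base, None, comp)[
            "comparator_coverage_complete_case"]
        for p in (0.2, 0.5, 0.9):
            masked = ct.inject_missingness(base, {"binet": p}, seed=1)
            cov = ct.coverage_comparison(masked, None, comp)[
                "comparator_coverage_complete_case"]
            assert cov <= cov_prev + 1e-12
            cov_prev = cov
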