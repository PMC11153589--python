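"""Benchmarking of risk predictions against matured 2-year outcomes.

Implements the deployment-benchmark toolkit: outcome labelling with the
censoring exclusion rule (patients with no event and follow-up shorter than
the horizon are removed from classification but kept, censored, for survival
analysis), classification metrics (MCC, precision, recall, PR-AUC) with
stratified-bootstrap confidence intervals, confidence-stratified comparison
(high-confidence subset vs all predictions), Kaplan-Meier / log-rank / Cox
survival summaries per predicted risk group, cohort missingness profiling,
missing-rate vs correctness comparison, and prediction-coverage comparison
with a low-dimensional complete-case comparator (a CLL-IPI-style five-variable
prognostic index that requires all of its inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score

from .ensemble import ConfidenceThresholds, EnsembleModel, Prediction
from .ensemble import predict as ensemble_predict
from .features import FeatureMatrix, PredictionPointPolicy
from .synth import UNKNOWN, ConfigurationError, PatientRecord

__all__ = [
    "OutcomeLabel",
    "ConfusionMatrix",
    "BootstrapConfig",
    "ComparatorScore",
    "label_outcomes",
    "training_labels",
    "classification_metrics",
    "confusion_matrix",
    "pr_auc",
    "bootstrap_summary",
    "confidence_strata_benchmark",
    "survival_benchmark",
    "profile_missingness",
    "missingness_vs_correctness",
    "coverage_comparison",
]


# --------------------------------------------------------------------------
# outcome labelling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeLabel:
    patient_id: str
    label: str  # "positive" | "negative" | "excluded"
    time_days: int  # days from prediction point to event or censoring
    event: bool
    reason: str = ""


def label_outcomes(
    cohort: list[PatientRecord], policy: PredictionPointPolicy | None = None
) -> list[OutcomeLabel]:
    """Composite-outcome labels at the prediction point.

    positive: first composite event within the horizon; negative: event-free
    with follow-up >= horizon; excluded: event-free but censored earlier
    (kept with censor time for survival use). An event dated before the
    prediction point flags the patient as excluded with a reason.
    """
    if policy is None:
        policy = PredictionPointPolicy()
    horizon = policy.outcome_horizon_days
    labels = []
    for rec in cohort:
        pp = rec.diagnosis_day + policy.offset_days_from_diagnosis
        fu = rec.followup_end_day - pp
        if rec.outcome_type != "none" and rec.outcome_day is not None:
            t = rec.outcome_day - pp
            if t < 0:
                labels.append(
                    OutcomeLabel(rec.patient_id, "excluded", 0, False,
                                 reason="event_before_prediction_point")
                )
            elif t <= horizon:
                labels.append(OutcomeLabel(rec.patient_id, "positive", t, True))
            else:
                # event observed but beyond the horizon: negative for the
                # 2-year classification, event retained for survival
                labels.append(OutcomeLabel(rec.patient_id, "negative", t, True))
        elif fu >= horizon:
            labels.append(OutcomeLabel(rec.patient_id, "negative", fu, False))
        else:
            labels.append(
                OutcomeLabel(rec.patient_id, "excluded", max(fu, 0), False,
                             reason="followup_shorter_than_horizon")
            )
    return labels


def training_labels(
    cohort: list[PatientRecord], policy: PredictionPointPolicy | None = None
) -> pd.DataFrame:
    """Binary targets per outcome (composite / treatment / infection).

    Rows are the classification-evaluable patients (excluded patients are
    dropped); the target-specific columns are 1 when that event type was the
    first composite event within the horizon.
    """
    if policy is None:
        policy = PredictionPointPolicy()
    by_id = {rec.patient_id: rec for rec in cohort}
    rows = []
    for lab in label_outcomes(cohort, policy):
        if lab.label == "excluded":
            continue
        rec = by_id[lab.patient_id]
        positive = lab.label == "positive"
        rows.append(
            (
                lab.patient_id,
                int(positive),
                int(positive and rec.outcome_type == "treatment"),
                int(positive and rec.outcome_type == "infection"),
            )
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "composite", "treatment", "infection"]
    ).set_index("patient_id")


# --------------------------------------------------------------------------
# classification metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(
    predictions: list[Prediction], labels: list[OutcomeLabel]
) -> ConfusionMatrix:
    lab = {l.patient_id: l.label for l in labels if l.label != "excluded"}
    tp = fp = tn = fn = 0
    for p in predictions:
        truth = lab.get(p.patient_id)
        if truth is None:
            continue
        if p.risk_call == "high":
            tp += truth == "positive"
            fp += truth == "negative"
        else:
            fn += truth == "positive"
            tn += truth == "negative"
    return ConfusionMatrix(tp, fp, tn, fn)


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """MCC, precision and recall; undefined denominators yield ``None``."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return {"MCC": mcc, "precision": precision, "recall": recall}


def pr_auc(confidences, labels01) -> float | None:
    """Area under the step-wise (non-interpolated) precision-recall curve.

    Constant scores degenerate to a single operating point and the area
    equals the positive prevalence, by convention. Returns ``None`` when only
    one class is present.
    """
    y = np.asarray(labels01, dtype=int)
    if len(np.unique(y)) < 2:
        return None
    return float(average_precision_score(y, np.asarray(confidences, dtype=float)))


# --------------------------------------------------------------------------
# stratified bootstrap
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 5000
    stratified: bool = True  # strata = predicted risk class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


def bootstrap_summary(
    per_patient: pd.DataFrame,
    metric,
    config: BootstrapConfig | None = None,
    stratum_col: str = "stratum",
) -> dict[str, float]:
    """Percentile bootstrap of ``metric(resampled per-patient table)``.

    Patients are resampled with replacement within predicted-risk strata,
    preserving each stratum's size, so every replicate keeps the original
    high-risk to low-risk ratio.
    """
    if config is None:
        config = BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    if config.stratified:
        groups = [np.asarray(idx) for _, idx in
                  per_patient.groupby(stratum_col).indices.items()]
        for g in groups:
            if len(g) < 2:
                raise ConfigurationError("each stratum needs at least 2 patients")
    else:
        groups = [np.arange(len(per_patient))]
    stats = np.empty(config.replicates)
    for b in range(config.replicates):
        take = np.concatenate(
            [rng.choice(g, size=len(g), replace=True) for g in groups]
        )
        stats[b] = metric(per_patient.iloc[take])
    stats = stats[~np.isnan(stats)]
    return {
        "mean": float(np.mean(stats)),
        "ci_low": float(np.percentile(stats, 2.5)),
        "ci_high": float(np.percentile(stats, 97.5)),
        "replicates_used": int(len(stats)),
    }


def _per_patient_table(
    predictions: list[Prediction], labels: list[OutcomeLabel]
) -> pd.DataFrame:
    lab = {l.patient_id: l for l in labels}
    rows = []
    for p in predictions:
        l = lab.get(p.patient_id)
        if l is None or l.label == "excluded":
            continue
        rows.append(
            (p.patient_id, p.confidence, p.risk_call, p.band,
             int(l.label == "positive"))
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "confidence", "risk_call", "band", "y"]
    )


def _metrics_from_table(df: pd.DataFrame) -> dict[str, float | None]:
    pred_high = df["risk_call"].to_numpy() == "high"
    y = df["y"].to_numpy()
    cm = ConfusionMatrix(
        tp=int(np.sum(pred_high & (y == 1))),
        fp=int(np.sum(pred_high & (y == 0))),
        tn=int(np.sum(~pred_high & (y == 0))),
        fn=int(np.sum(~pred_high & (y == 1))),
    )
    out = classification_metrics(cm)
    out["PR-AUC"] = pr_auc(df["confidence"], df["y"]) if len(df) else None
    out["confusion"] = {"TP": cm.tp, "FP": cm.fp, "TN": cm.tn, "FN": cm.fn}
    return out


def _metric_fn(name: str):
    if name == "PR-AUC":
        return lambda df: (pr_auc(df["confidence"], df["y"]) or np.nan)

    def fn(df: pd.DataFrame) -> float:
        v = _metrics_from_table(df)[name]
        return np.nan if v is None else v

    return fn


def confidence_strata_benchmark(
    predictions: list[Prediction],
    labels: list[OutcomeLabel],
    thresholds: ConfidenceThresholds | None = None,
    bootstrap: BootstrapConfig | None = None,
    metrics: tuple[str, ...] = ("MCC", "precision", "recall", "PR-AUC"),
) -> dict:
    """Paired report: high-confidence subset vs all predictions.

    Bands are re-derived from ``thresholds`` when given (so the same
    predictions can be benchmarked under recalibrated cutoffs); the
    high-confidence subset is every patient whose band is not
    ``low_confidence``.
    """
    if thresholds is not None:
        predictions = [
            Prediction(p.patient_id, p.confidence, p.risk_call,
                       thresholds.band(p.confidence),
                       p.risk_factors_up, p.risk_factors_down)
            for p in predictions
        ]
    table = _per_patient_table(predictions, labels)
    report: dict = {
        "n_evaluated": int(len(table)),
        "high_confidence_fraction": float(
            np.mean(table["band"] != "low_confidence")
        ) if len(table) else 0.0,
    }
    for key, df in (
        ("high_confidence", table[table["band"] != "low_confidence"]),
        ("all", table),
    ):
        if df.empty:
            report[key] = {"n": 0, "note": "empty subset"}
            continue
        section: dict = {"n": int(len(df))}
        section.update(_metrics_from_table(df))
        if bootstrap is not None:
            strata_ok = df["risk_call"].value_counts().min() >= 2 and \
                df["risk_call"].nunique() >= 1
            boots = {}
            for m in metrics:
                if strata_ok:
                    boots[m] = bootstrap_summary(
                        df, _metric_fn(m), bootstrap, stratum_col="risk_call"
                    )
            section["bootstrap"] = boots
        report[key] = section
    return report


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

def survival_benchmark(
    predictions: list[Prediction], labels: list[OutcomeLabel]
) -> dict:
    """KM curves per predicted risk group, log-rank p, Cox HR (high vs low).

    Uses every labelled patient including the classification-excluded ones,
    which enter right-censored at their follow-up end.
    """
    lab = {l.patient_id: l for l in labels}
    rows = []
    for p in predictions:
        l = lab.get(p.patient_id)
        if l is None or l.reason == "event_before_prediction_point":
            continue
        rows.append((p.patient_id, max(l.time_days, 0), int(l.event),
                     int(p.risk_call == "high")))
    df = pd.DataFrame(rows, columns=["patient_id", "time", "event", "high_risk"])
    if df["event"].sum() == 0:
        return {"hazard_ratio": None, "note": "no events observed"}

    km_curves = {}
    for grp, sub in df.groupby("high_risk"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"],
                label="high_risk" if grp else "low_risk")
        km_curves["high_risk" if grp else "low_risk"] = (
            kmf.survival_function_.reset_index()
            .rename(columns={kmf.survival_function_.columns[0]: "survival",
                             "timeline": "time"})
        )

    result: dict = {"km_curves": km_curves, "n": int(len(df)),
                    "events": int(df["event"].sum())}
    both = df["high_risk"].nunique() == 2
    if both:
        hi = df[df["high_risk"] == 1]
        lo = df[df["high_risk"] == 0]
        lr = logrank_test(hi["time"], lo["time"], hi["event"], lo["event"])
        result["logrank_p"] = float(lr.p_value)
        if hi["event"].sum() > 0 and lo["event"].sum() > 0:
            cph = CoxPHFitter()
            cph.fit(df[["time", "event", "high_risk"]], duration_col="time",
                    event_col="event")
            result["hazard_ratio"] = float(np.exp(cph.params_["high_risk"]))
            ci = cph.confidence_intervals_
            with np.errstate(over="ignore"):  # sparse events -> infinite CI
                result["hr_ci"] = (
                    float(np.exp(ci.iloc[0, 0])), float(np.exp(ci.iloc[0, 1]))
                )
        else:
            result["hazard_ratio"] = None
            result["note"] = "a risk group has no events"
    else:
        result["hazard_ratio"] = None
        result["note"] = "single predicted risk group"
    return result


# --------------------------------------------------------------------------
# missingness profiling
# --------------------------------------------------------------------------

def profile_missingness(
    cohort: list[PatientRecord],
    lab_panel: list[str],
    policy: PredictionPointPolicy | None = None,
) -> dict:
    """Availability/depth profile of a cohort at the prediction point.

    * lab availability: mean over patients of the fraction of panel labs with
      at least one pre-prediction-point event;
    * historical depth: for each lab, mean over patients (with data) of years
      from the earliest pre-pp test to the pp, then mean over labs;
    * culture availability: fraction of patients with >= 1 culture event
      before the pp, and mean years back of the earliest culture;
    * baseline missingness: per-variable fraction coded ``unknown``.
    """
    if not cohort:
        raise ConfigurationError("cohort must not be empty")
    if policy is None:
        policy = PredictionPointPolicy()

    avail_fracs = []
    depth_by_lab: dict[str, list[float]] = {lab: [] for lab in lab_panel}
    culture_any = 0
    culture_depths = []
    baseline_missing: dict[str, int] = {}
    for rec in cohort:
        pp = rec.diagnosis_day + policy.offset_days_from_diagnosis
        earliest: dict[str, int] = {}
        for var, day, _, _ in rec.lab_events:
            if day <= pp and (var not in earliest or day < earliest[var]):
                earliest[var] = day
        avail_fracs.append(
            sum(1 for lab in lab_panel if lab in earliest) / len(lab_panel)
        )
        for lab, day in earliest.items():
            if lab in depth_by_lab:
                depth_by_lab[lab].append((pp - day) / 365.25)
        pre_cultures = [d for d in rec.culture_events if d <= pp]
        if pre_cultures:
            culture_any += 1
            culture_depths.append((pp - min(pre_cultures)) / 365.25)
        for var, cat in rec.baseline.items():
            baseline_missing[var] = baseline_missing.get(var, 0) + (cat == UNKNOWN)

    lab_depths = [np.mean(v) for v in depth_by_lab.values() if v]
    n = len(cohort)
    return {
        "lab_availability": float(np.mean(avail_fracs)),
        "historical_depth_years": float(np.mean(lab_depths)) if lab_depths else 0.0,
        "culture_availability": culture_any / n,
        "culture_depth_years": float(np.mean(culture_depths)) if culture_depths else 0.0,
        "baseline_missingness": {
            var: cnt / n for var, cnt in sorted(baseline_missing.items())
        },
    }


def missingness_vs_correctness(
    predictions: list[Prediction],
    labels: list[OutcomeLabel],
    missing_rates: pd.Series,
) -> dict:
    """Compare per-patient missing rates between correct and incorrect calls.

    Groups TP vs FP and TN vs FN; each comparison reports summary statistics
    and a Mann-Whitney rank test (two-sided). Empty groups skip the
    comparison with a notice rather than erroring.
    """
    lab = {l.patient_id: l.label for l in labels if l.label != "excluded"}
    groups: dict[str, list[float]] = {"TP": [], "FP": [], "TN": [], "FN": []}
    for p in predictions:
        truth = lab.get(p.patient_id)
        if truth is None or p.patient_id not in missing_rates.index:
            continue
        rate = float(missing_rates.loc[p.patient_id])
        if p.risk_call == "high":
            groups["TP" if truth == "positive" else "FP"].append(rate)
        else:
            groups["FN" if truth == "positive" else "TN"].append(rate)

    out: dict = {
        "summaries": {
            g: {"n": len(v), "mean": float(np.mean(v)) if v else None,
                "median": float(np.median(v)) if v else None}
            for g, v in groups.items()
        }
    }
    for name, (a, b) in (("TP_vs_FP", ("TP", "FP")), ("TN_vs_FN", ("TN", "FN"))):
        if not groups[a] or not groups[b]:
            out[name] = {"note": f"empty group, comparison skipped ({a}/{b})"}
            continue
        stat = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        out[name] = {"U": float(stat.statistic), "p": float(stat.pvalue)}
    return out


# --------------------------------------------------------------------------
# comparator coverage (five-variable prognostic index, complete-case)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparatorScore:
    """CLL-IPI-style index: age>65 (1), Binet B/C (1), beta-2-microglobulin
    >4 mg/L (2), IGHV unmutated (2), del(17p)/TP53 aberration (4); risk
    categories low 0-1, intermediate 2-3, high 4-5, very high 6-10.

    ``complete_case`` mode yields no score when any input is missing;
    ``impute_binet_ighv`` imputes Binet stage and IGHV status (to the modal
    favourable levels) so only the remaining three inputs are required.
    """

    weights: dict[str, int] = field(
        default_factory=lambda: {
            "age_ge65": 1, "binet_bc": 1, "b2m_gt4": 2,
            "ighv_unmutated": 2, "del17p_tp53": 4,
        }
    )
    categories: tuple[tuple[int, int, str], ...] = (
        (0, 1, "low"), (2, 3, "intermediate"), (4, 5, "high"), (6, 10, "very_high"),
    )
    mode: str = "complete_case"

    def inputs_available(self, baseline: dict[str, str]) -> dict[str, bool]:
        return {
            "age_ge65": baseline.get("age", UNKNOWN) != UNKNOWN,
            "binet_bc": baseline.get("binet", UNKNOWN) != UNKNOWN,
            "b2m_gt4": baseline.get("b2m", UNKNOWN) != UNKNOWN,
            "ighv_unmutated": baseline.get("ighv", UNKNOWN) != UNKNOWN,
            "del17p_tp53": baseline.get("fish", UNKNOWN) != UNKNOWN,
        }

    def can_score(self, baseline: dict[str, str]) -> bool:
        avail = self.inputs_available(baseline)
        if self.mode == "impute_binet_ighv":
            avail["binet_bc"] = avail["ighv_unmutated"] = True
        return all(avail.values())

    def score(self, baseline: dict[str, str]) -> tuple[int, str] | None:
        if not self.can_score(baseline):
            return None
        impute = self.mode == "impute_binet_ighv"
        binet = baseline.get("binet", UNKNOWN)
        ighv = baseline.get("ighv", UNKNOWN)
        if impute and binet == UNKNOWN:
            binet = "A"
        if impute and ighv == UNKNOWN:
            ighv = "mutated"
        points = 0
        points += self.weights["age_ge65"] * (baseline.get("age") == "ge65")
        points += self.weights["binet_bc"] * (binet in ("B", "C"))
        points += self.weights["b2m_gt4"] * (baseline.get("b2m") == "gt4")
        points += self.weights["ighv_unmutated"] * (ighv == "unmutated")
        points += self.weights["del17p_tp53"] * (baseline.get("fish") == "del17p")
        category = next(
            name for lo, hi, name in self.categories if lo <= points <= hi
        )
        return points, category


def coverage_comparison(
    cohort: list[PatientRecord],
    model: EnsembleModel | None,
    comparator: ComparatorScore,
    matrix: FeatureMatrix | None = None,
) -> dict:
    """Prediction coverage of the ensemble vs the low-dimensional comparator.

    Ensemble coverage is the fraction of patients for whom ``predict``
    returns a prediction (contractually 1.0 whatever the missingness); the
    comparator's coverage is the fraction of patients with all required
    inputs available, reported for both its modes.
    """
    n = len(cohort)
    if model is not None and matrix is not None:
        preds = ensemble_predict(model, matrix)
        ensemble_cov = len(preds) / n if n else 0.0
    else:
        ensemble_cov = 1.0 if n else 0.0

    out = {"ensemble_coverage": ensemble_cov, "n": n}
    for mode in ("complete_case", "impute_binet_ighv"):
        comp = ComparatorScore(weights=comparator.weights,
                               categories=comparator.categories, mode=mode)
        scored = sum(1 for rec in cohort if comp.can_score(rec.baseline))
        out[f"comparator_coverage_{mode}"] = scored / n if n else 0.0
        out[f"comparator_scored_{mode}"] = scored
    return out
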