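"""Dictionary-based data harmonization validated by prediction matching.

Porting a trained model to a new EHR requires mapping that source's variable
labels and units onto the model's canonical vocabulary. Two many-to-one
dictionaries drive the translation: a name map (source label -> canonical
variable) and a unit map ((canonical variable, source unit) -> (factor,
offset), with canonical = factor * source + offset). Rows whose labels or
units are not covered are routed to an unmapped-rows report, never silently
dropped.

Correctness of the dictionaries is validated the way it was done in practice:
run the model on the same patients from both sources and require a perfect
match of its three outputs — risk call, confidence (default tolerance 0, i.e.
bit-identical) and the ranked top-5 up/down personalized risk factors. When
patients mismatch, the per-feature contribution vectors of the two sources
are differenced to implicate features, which the registry maps back to
variables so a human can fix the offending dictionary entry; the
harmonize -> match -> localize loop iterates until a perfect match or an
iteration cap (dictionary edits are external, human-in-the-loop inputs
between iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import (
    ConfidenceThresholds,
    EnsembleModel,
    attribute_risk_factors,
    predict as ensemble_predict,
    top_risk_factors,
)
from .features import FeatureMatrix, PredictionPointPolicy, extract_features
from .synth import ConfigurationError, PatientRecord, cohort_from_tables

__all__ = [
    "MatchReport",
    "harmonize",
    "match_predictions",
    "localize_discrepancies",
    "harmonization_cycle",
    "name_map_from_frame",
    "unit_map_from_frame",
]


def name_map_from_frame(df: pd.DataFrame) -> dict[str, str]:
    """Read a (source_label, canonical) dictionary table."""
    return dict(zip(df["source_label"], df["canonical"]))


def unit_map_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    """Read a (variable, source_unit, factor, offset) dictionary table."""
    return {
        (r.variable, r.source_unit): (float(r.factor), float(r.offset))
        for r in df.itertuples(index=False)
    }


def harmonize(
    raw_tables: dict[str, pd.DataFrame],
    name_map: dict[str, str],
    unit_map: dict[tuple[str, str], tuple[float, float]],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Canonicalize raw source tables; returns (tables, unmapped_rows).

    Unknown source labels pass through the name map unchanged only if they
    already are canonical (identity fallback is NOT applied: uncovered labels
    are reported). Lab units without a unit-map entry are assumed canonical
    when the unit string already matches; otherwise the row is reported.
    """
    for key, (factor, _) in unit_map.items():
        if factor == 0:
            raise ConfigurationError(f"unit factor for {key} is zero")

    unmapped: list[tuple[str, str, str]] = []  # (table, label, reason)

    baseline = raw_tables["baseline"].copy()
    baseline["variable"] = [
        name_map.get(v, v) for v in baseline["variable"]
    ]

    labs = raw_tables["labs"].copy()
    new_var, new_val, new_unit, keep = [], [], [], []
    for row in labs.itertuples(index=False):
        canon = name_map.get(row.variable, row.variable)
        key = (canon, row.unit)
        if key in unit_map:
            factor, offset = unit_map[key]
            new_var.append(canon)
            new_val.append(factor * row.value + offset)
            # the dictionary does not carry the canonical unit label; values
            # are canonical while the label keeps its source spelling
            new_unit.append(row.unit)
            keep.append(True)
        else:
            # unit already canonical for this variable, or uncovered
            known_units = {u for (v, u) in unit_map if v == canon}
            if known_units:
                unmapped.append(("labs", f"{row.variable}[{row.unit}]",
                                 "unit not in dictionary"))
                keep.append(False)
            else:
                new_var.append(canon)
                new_val.append(row.value)
                new_unit.append(row.unit)
                keep.append(True)
    labs = labs[np.asarray(keep, dtype=bool)].copy()
    labs["variable"] = new_var
    labs["value"] = new_val
    labs["unit"] = new_unit

    tables = {
        "baseline": baseline,
        "labs": labs,
        "cultures": raw_tables["cultures"].copy(),
        "outcomes": raw_tables["outcomes"].copy(),
    }
    unmapped_df = pd.DataFrame(unmapped, columns=["table", "label", "reason"])
    return tables, unmapped_df


@dataclass
class MatchReport:
    per_patient: pd.DataFrame  # patient_id, risk_match, delta_confidence, factors_match
    matched_fraction: float
    implicated_features: list[str] = field(default_factory=list)
    implicated_variables: list[str] = field(default_factory=list)

    @property
    def mismatched_patients(self) -> list[str]:
        df = self.per_patient
        return list(df.loc[~df["matched"], "patient_id"])

    def to_dict(self) -> dict:
        return {
            "matched_fraction": self.matched_fraction,
            "n_patients": int(len(self.per_patient)),
            "mismatched_patients": self.mismatched_patients,
            "implicated_features": self.implicated_features,
            "implicated_variables": self.implicated_variables,
        }


def _predict_with_factors(
    model: EnsembleModel,
    cohort: list[PatientRecord],
    policy: PredictionPointPolicy,
    thresholds: ConfidenceThresholds | None,
) -> tuple[dict, pd.DataFrame]:
    matrix = extract_features(cohort, model.registry, policy)
    preds = ensemble_predict(model, matrix, thresholds)
    contrib = attribute_risk_factors(model, matrix)
    by_id = {}
    for p in preds:
        up, down = top_risk_factors(contrib.loc[p.patient_id])
        by_id[p.patient_id] = (p.risk_call, p.confidence, up, down)
    return by_id, contrib, matrix.values


def match_predictions(
    model: EnsembleModel,
    cohort_a: list[PatientRecord],
    cohort_b: list[PatientRecord],
    policy: PredictionPointPolicy | None = None,
    thresholds: ConfidenceThresholds | None = None,
    tol: float = 0.0,
) -> MatchReport:
    """Per-patient comparison of the model's three outputs across sources.

    A patient matches iff the risk calls are equal, |delta confidence| <= tol
    (tol = 0 demands bit-identical confidences) and the top-5 up and down
    risk-factor lists are identical in membership and order.
    """
    if policy is None:
        policy = PredictionPointPolicy()
    ids_a = {r.patient_id for r in cohort_a}
    ids_b = {r.patient_id for r in cohort_b}
    if ids_a != ids_b:
        raise ConfigurationError(
            f"patient ids differ between sources: {sorted(ids_a ^ ids_b)}"
        )
    a, contrib_a, values_a = _predict_with_factors(model, cohort_a, policy, thresholds)
    b, contrib_b, values_b = _predict_with_factors(model, cohort_b, policy, thresholds)

    rows = []
    for pid in sorted(ids_a):
        risk_a, conf_a, up_a, down_a = a[pid]
        risk_b, conf_b, up_b, down_b = b[pid]
        risk_match = risk_a == risk_b
        dconf = abs(conf_a - conf_b)
        factors_match = (
            [f for f, _ in up_a] == [f for f, _ in up_b]
            and [f for f, _ in down_a] == [f for f, _ in down_b]
        )
        rows.append(
            (pid, risk_match, dconf, factors_match,
             risk_match and dconf <= tol and factors_match)
        )
    per_patient = pd.DataFrame(
        rows,
        columns=["patient_id", "risk_match", "delta_confidence",
                 "factors_match", "matched"],
    )
    report = MatchReport(
        per_patient=per_patient,
        matched_fraction=float(per_patient["matched"].mean()) if len(per_patient)
        else 1.0,
    )
    if not per_patient["matched"].all():
        feats, variables = _localize(contrib_a, contrib_b, values_a, values_b,
                                     model, report.mismatched_patients, tol)
        report.implicated_features = feats
        report.implicated_variables = variables
    return report


def _localize(contrib_a, contrib_b, values_a, values_b, model, mismatched, tol):
    diff = (contrib_a.loc[mismatched] - contrib_b.loc[mismatched]).abs()
    counts = (diff > tol).sum(axis=0)
    magnitude = diff.sum(axis=0)
    implicated = counts[counts > 0]
    feats = sorted(
        implicated.index, key=lambda f: (-implicated[f], -magnitude[f], f)
    )
    # a model's nonlinearity spreads contribution discrepancies onto clean
    # variables; inspecting the raw inputs behind implicated features — as
    # the manual workflow does — separates the true offender, so variables
    # whose own feature values differ across sources rank in a first tier
    va = values_a.loc[mismatched]
    vb = values_b.loc[mismatched]
    value_differs = ~((va == vb) | (va.isna() & vb.isna()))
    var_of = {s.feature_id: s.variable for s in model.registry}
    var_patients: dict[str, set] = {}
    var_magnitude: dict[str, float] = {}
    var_value_diff: dict[str, bool] = {}
    affected = diff > tol
    for f in feats:
        v = var_of[f]
        var_patients.setdefault(v, set()).update(
            diff.index[affected[f]].tolist()
        )
        var_magnitude[v] = var_magnitude.get(v, 0.0) + float(magnitude[f])
        var_value_diff[v] = var_value_diff.get(v, False) or bool(
            value_differs[f].any()
        )
    variables = sorted(
        var_patients,
        key=lambda v: (
            not var_value_diff[v],
            -len(var_patients[v]),
            -var_magnitude[v],
            v,
        ),
    )
    return feats, variables


def localize_discrepancies(
    model: EnsembleModel,
    cohort_a: list[PatientRecord],
    cohort_b: list[PatientRecord],
    mismatched_patients: list[str],
    policy: PredictionPointPolicy | None = None,
    tol: float = 0.0,
) -> dict:
    """Implicate the variables behind per-patient contribution mismatches.

    Features whose contributions differ by more than ``tol`` for any
    mismatched patient are implicated and mapped to variables via the
    registry, ranked by the number of affected patients.
    """
    if policy is None:
        policy = PredictionPointPolicy()
    if not mismatched_patients:
        raise ConfigurationError("need at least one mismatched patient")
    matrix_a = extract_features(cohort_a, model.registry, policy)
    matrix_b = extract_features(cohort_b, model.registry, policy)
    contrib_a = attribute_risk_factors(model, matrix_a)
    contrib_b = attribute_risk_factors(model, matrix_b)
    feats, variables = _localize(contrib_a, contrib_b,
                                 matrix_a.values, matrix_b.values,
                                 model, mismatched_patients, tol)
    return {"features": feats, "variables": variables}


def harmonization_cycle(
    raw_tables: dict[str, pd.DataFrame],
    name_map: dict[str, str],
    unit_map: dict[tuple[str, str], tuple[float, float]],
    reference_cohort: list[PatientRecord],
    model: EnsembleModel,
    policy: PredictionPointPolicy | None = None,
    tol: float = 0.0,
    max_iters: int = 3,
    map_updates=None,
) -> dict:
    """Iterate harmonize -> match -> localize until perfect match.

    ``map_updates(iteration, report, name_map, unit_map)`` is the
    human-in-the-loop hook: it may return revised ``(name_map, unit_map)``
    dictionaries between iterations, or None to keep them. Returns a status
    ('converged' | 'unconverged'), the final report and a per-iteration
    audit trail.
    """
    if policy is None:
        policy = PredictionPointPolicy()
    audit = []
    status = "unconverged"
    report = None
    for iteration in range(1, max_iters + 1):
        tables, unmapped = harmonize(raw_tables, name_map, unit_map)
        cohort = cohort_from_tables(tables)
        report = match_predictions(model, reference_cohort, cohort,
                                   policy=policy, tol=tol)
        audit.append(
            {
                "iteration": iteration,
                "matched_fraction": report.matched_fraction,
                "unmapped_rows": int(len(unmapped)),
                "implicated_variables": report.implicated_variables,
            }
        )
        if report.matched_fraction == 1.0:
            status = "converged"
            break
        if map_updates is not None:
            revised = map_updates(iteration, report, name_map, unit_map)
            if revised is not None:
                name_map, unit_map = revised
    return {"status": status, "report": report, "audit": audit,
            "iterations": len(audit)}
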