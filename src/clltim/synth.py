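"""Synthetic longitudinal EHR cohorts for a CLL prognostic-model deployment.

Real patient-level EHR extracts cannot be shared, so every downstream stage of
the pipeline (feature extraction, ensemble training, benchmarking,
harmonization, monitoring) is exercised against simulated cohorts that emulate
the relevant *structure* of the data: categorical baseline markers with
configurable prevalences, log-normal laboratory time series of configurable
historical depth, blood-culture event streams, a competing-risks composite
outcome (first of severe infection or CLL treatment) with a tunable 2-year
rate, administrative censoring, and per-variable structured-data missingness.

Two presets bundle the study conditions of the two environments the model has
lived in:

``research``
    the development environment — long (~10-year) laboratory histories, fully
    structured staging variables, composite 2-year event rate ~33%.
``deployment``
    the production environment — short (<1-year) laboratory histories, heavy
    missingness of structured baseline markers (Binet 72.2%, IGHV 91.1%,
    beta-2-microglobulin 35.8%, FISH 99.5%, ECOG 100%), composite 2-year
    event rate ~40.6%.

All dates are integer day offsets from a fixed epoch; calendar arithmetic is
deliberately avoided.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ConfigurationError",
    "LabDef",
    "OutcomeParams",
    "CohortSpec",
    "PatientRecord",
    "SourceDialect",
    "research_preset",
    "deployment_preset",
    "default_lab_panel",
    "generate_cohort",
    "inject_missingness",
    "render_source",
    "cohort_to_tables",
    "cohort_from_tables",
    "write_cohort",
    "UNKNOWN",
]

#: explicit category used for a structurally missing baseline value
UNKNOWN = "unknown"

#: day of the prediction point relative to diagnosis (~3 months)
PREDICTION_POINT_OFFSET_DAYS = 92

DAYS_PER_YEAR = 365.25


class ConfigurationError(ValueError):
    """A cohort/ensemble specification violates its invariants."""


# --------------------------------------------------------------------------
# specification types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LabDef:
    """One laboratory variable: canonical name/unit and sampling model.

    Values are drawn i.i.d. log-normal (stationary series; autocorrelation is
    out of scope) with ``per_year_rate`` tests per patient-year.
    """

    name: str
    unit: str
    log_mean: float
    log_sd: float
    per_year_rate: float = 4.0


@dataclass(frozen=True)
class OutcomeParams:
    """Competing-risks outcome model: two cause-specific exponential clocks.

    Each patient's total hazard is ``(h_inf + h_trt) * exp(lp)`` where ``lp``
    is a linear predictor over baseline covariates; the firing clock decides
    the composite-event type with probability ``h_inf / (h_inf + h_trt)``.
    If ``target_2yr_rate`` is set, both baseline hazards are rescaled by a
    common factor (solved on the drawn cohort) so that the expected fraction
    of composite events within 2 years of the prediction point equals the
    target.
    """

    coefficients: dict[str, float]
    base_hazard_infection: float  # events / patient-year at lp = 0
    base_hazard_treatment: float
    target_2yr_rate: float | None = None
    censor_min_days: int = 365
    censor_max_days: int = 2190


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    seed: int
    baseline_prevalences: dict[str, dict[str, float]]
    lab_panel: tuple[LabDef, ...]
    history_depth_years: tuple[float, float]  # (min, max) uniform
    culture_rate: float  # blood-culture events per patient-year
    culture_history_years: float
    outcome_params: OutcomeParams
    missingness_profile: dict[str, float] = field(default_factory=dict)
    name: str = "custom"

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be nonnegative")
        if not self.lab_panel:
            raise ConfigurationError("lab_panel must contain at least one variable")
        for var, dist in self.baseline_prevalences.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"baseline distribution for {var!r} sums to {total}, not 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"negative probability in {var!r}")
        for var, p in self.missingness_profile.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"missingness probability for {var!r} is {p}, outside [0,1]"
                )
        if self.culture_rate < 0:
            raise ConfigurationError("culture_rate must be >= 0")
        lo, hi = self.history_depth_years
        if lo < 0 or hi < lo:
            raise ConfigurationError("history_depth_years must satisfy 0 <= lo <= hi")
        op = self.outcome_params
        if op.base_hazard_infection < 0 or op.base_hazard_treatment < 0:
            raise ConfigurationError("baseline hazards must be >= 0")


@dataclass
class PatientRecord:
    """One patient's baseline values, event streams and outcome.

    ``latent_*`` fields are generator-side ground truth (the uncensored event
    time/type and the linear-predictor risk) and are never written to the
    exported source tables — only to a separate truth file.
    """

    patient_id: str
    diagnosis_day: int
    baseline: dict[str, str]
    lab_events: list[tuple[str, int, float, str]]  # (variable, day, value, unit)
    culture_events: list[int]
    outcome_type: str  # "infection" | "treatment" | "none"
    outcome_day: int | None
    followup_end_day: int
    latent_risk: float = 0.0
    latent_event_day: int | None = None
    latent_event_type: str = "none"

    @property
    def prediction_point_day(self) -> int:
        return self.diagnosis_day + PREDICTION_POINT_OFFSET_DAYS


@dataclass(frozen=True)
class SourceDialect:
    """Rendering rules of one EHR source: scrambled labels and units.

    ``unit_scramble`` maps a canonical (variable, unit) to
    ``(source_unit, factor, offset)`` such that
    ``canonical = factor * source + offset``; rendering applies the inverse.
    ``corruption`` optionally overrides (factor, offset) for named variables,
    emulating a wrong mapping-dictionary entry.
    """

    name_scramble: dict[str, str] = field(default_factory=dict)
    unit_scramble: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    corruption: dict[str, tuple[float, float]] = field(default_factory=dict)

    def source_name(self, canonical: str) -> str:
        return self.name_scramble.get(canonical, canonical)

    def to_maps(self) -> tuple[dict[str, str], dict[tuple[str, str], tuple[float, float]]]:
        """The correct harmonization dictionaries for this dialect."""
        name_map = {src: canon for canon, src in self.name_scramble.items()}
        unit_map = {}
        for canon_var, (src_unit, factor, offset) in self.unit_scramble.items():
            unit_map[(canon_var, src_unit)] = (factor, offset)
        return name_map, unit_map


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

_DEFAULT_LAB_NAMES = [
    # a 33-variable routine panel (hematology, biochemistry, immunology)
    ("hemoglobin", "g/dL", 2.56, 0.12),
    ("leukocytes", "1e9/L", 2.48, 0.55),
    ("lymphocytes", "1e9/L", 2.30, 0.80),
    ("neutrophils", "1e9/L", 1.25, 0.45),
    ("monocytes", "1e9/L", -0.60, 0.45),
    ("eosinophils", "1e9/L", -1.80, 0.70),
    ("basophils", "1e9/L", -3.00, 0.60),
    ("platelets", "1e9/L", 5.35, 0.30),
    ("erythrocytes", "1e12/L", 1.50, 0.12),
    ("hematocrit", "%", 3.72, 0.10),
    ("mcv", "fL", 4.50, 0.06),
    ("reticulocytes", "1e9/L", 4.10, 0.35),
    ("creatinine", "umol/L", 4.40, 0.25),
    ("urea", "mmol/L", 1.80, 0.35),
    ("sodium", "mmol/L", 4.94, 0.02),
    ("potassium", "mmol/L", 1.42, 0.07),
    ("calcium", "mmol/L", 0.85, 0.06),
    ("albumin", "g/L", 3.68, 0.10),
    ("bilirubin", "umol/L", 2.20, 0.45),
    ("alat", "U/L", 3.20, 0.45),
    ("alkaline_phosphatase", "U/L", 4.30, 0.30),
    ("ldh", "U/L", 5.30, 0.25),
    ("crp", "mg/L", 1.20, 1.00),
    ("igg", "g/L", 2.25, 0.35),
    ("iga", "g/L", 0.55, 0.60),
    ("igm", "g/L", -0.35, 0.70),
    ("beta2_microglobulin", "mg/L", 0.85, 0.40),
    ("ferritin", "ug/L", 4.80, 0.70),
    ("transferrin", "g/L", 0.90, 0.15),
    ("haptoglobin", "g/L", 0.10, 0.50),
    ("glucose", "mmol/L", 1.70, 0.20),
    ("amylase", "U/L", 4.00, 0.35),
    ("coagulation_inr", "ratio", 0.05, 0.10),
]


def default_lab_panel(per_year_rate: float = 4.0) -> tuple[LabDef, ...]:
    """The default 33-variable routine laboratory panel."""
    return tuple(
        LabDef(name, unit, mu, sd, per_year_rate)
        for name, unit, mu, sd in _DEFAULT_LAB_NAMES
    )


# log hazard ratios in line with published CLL prognostic effect sizes
# (IGHV-unmutated ~2.6x, beta-2-microglobulin >4 ~2x, del(17p) ~4x,
# age >=65 ~1.7x, advanced stage ~2-3x)
_OUTCOME_COEFFICIENTS = {
    "ighv=unmutated": 0.96,
    "binet=B": 0.55,
    "binet=C": 1.10,
    "b2m=gt4": 0.70,
    "fish=del17p": 1.40,
    "age=ge65": 0.53,
    "ecog=2plus": 0.50,
}

# FISH-hierarchy and ECOG prevalences are not published for these cohorts;
# values below are typical for newly diagnosed CLL.
_FISH_DIST = {"del13q": 0.40, "normal": 0.25, "tri12": 0.15, "del11q": 0.12, "del17p": 0.08}
_ECOG_DIST = {"0": 0.60, "1": 0.30, "2plus": 0.10}


def research_preset(n_patients: int = 3720, seed: int = 0) -> CohortSpec:
    """Development-environment conditions: long histories, structured staging."""
    rate = 0.33
    return CohortSpec(
        n_patients=n_patients,
        seed=seed,
        baseline_prevalences={
            "age": {"lt65": 0.299, "ge65": 0.701},
            "sex": {"female": 0.398, "male": 0.602},
            "binet": {"A": 0.854, "B": 0.119, "C": 0.027},
            "ighv": {"mutated": 0.703, "unmutated": 0.297},
            "b2m": {"le4": 0.880, "gt4": 0.120},
            "fish": dict(_FISH_DIST),
            "ecog": dict(_ECOG_DIST),
        },
        lab_panel=default_lab_panel(),
        history_depth_years=(8.0, 12.0),
        culture_rate=0.30,
        culture_history_years=10.0,
        outcome_params=OutcomeParams(
            coefficients=dict(_OUTCOME_COEFFICIENTS),
            base_hazard_infection=0.10 * (18.1 / 33.0) * 2,
            base_hazard_treatment=0.10 * (14.9 / 33.0) * 2,
            target_2yr_rate=rate,
        ),
        missingness_profile={
            "binet": 0.0,
            "b2m": 0.236,
            "ighv": 0.211,
            "fish": 0.0,
            "ecog": 0.004,
        },
        name="research",
    )


def deployment_preset(n_patients: int = 1099, seed: int = 0) -> CohortSpec:
    """Production-environment conditions: short histories, heavy missingness."""
    rate = 0.406
    return CohortSpec(
        n_patients=n_patients,
        seed=seed,
        baseline_prevalences={
            "age": {"lt65": 0.236, "ge65": 0.764},
            "sex": {"female": 0.403, "male": 0.597},
            "binet": {"A": 0.881, "B": 0.065, "C": 0.054},
            "ighv": {"mutated": 0.702, "unmutated": 0.298},
            "b2m": {"le4": 0.848, "gt4": 0.152},
            "fish": dict(_FISH_DIST),
            "ecog": dict(_ECOG_DIST),
        },
        lab_panel=default_lab_panel(),
        history_depth_years=(0.3, 1.5),
        culture_rate=0.30,
        culture_history_years=1.0,
        outcome_params=OutcomeParams(
            coefficients=dict(_OUTCOME_COEFFICIENTS),
            base_hazard_infection=0.13 * (23.2 / 40.6) * 2,
            base_hazard_treatment=0.13 * (17.5 / 40.6) * 2,
            target_2yr_rate=rate,
        ),
        missingness_profile={
            "binet": 0.722,
            "b2m": 0.358,
            "ighv": 0.911,
            "fish": 0.995,
            "ecog": 1.0,
        },
        name="deployment",
    )


PRESETS = {"research": research_preset, "deployment": deployment_preset}


def get_preset(name: str, n_patients: int | None = None, seed: int = 0) -> CohortSpec:
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; known presets: {sorted(PRESETS)}"
        )
    spec = PRESETS[name](seed=seed) if n_patients is None else PRESETS[name](n_patients, seed)
    return spec


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _linear_predictor(baseline: dict[str, str], coefficients: dict[str, float]) -> float:
    lp = 0.0
    for key, coef in coefficients.items():
        var, _, level = key.partition("=")
        if baseline.get(var) == level:
            lp += coef
    return lp


def _calibrate_scale(rates: np.ndarray, horizon_years: float, target: float) -> float:
    """Common factor s with mean(1 - exp(-horizon * s * rates)) == target."""

    def f(log_s: float) -> float:
        return float(np.mean(1.0 - np.exp(-horizon_years * math.exp(log_s) * rates))) - target

    return math.exp(brentq(f, -12.0, 12.0, xtol=1e-12))


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort of longitudinal patient records.

    The composite outcome is the first event of two cause-specific exponential
    clocks started at the prediction point, with log-linear covariate effects;
    administrative censoring truncates observation. Identical ``(spec, seed)``
    reproduce identical cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if n == 0:
        return []

    # baseline covariates
    baselines: list[dict[str, str]] = []
    for _ in range(n):
        baselines.append({})
    for var, dist in spec.baseline_prevalences.items():
        levels = list(dist.keys())
        probs = np.asarray([dist[l] for l in levels], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(levels), size=n, p=probs)
        for i, d in enumerate(draws):
            baselines[i][var] = levels[d]

    diagnosis_days = rng.integers(3653, 4653, size=n)  # ~year 10-12 of the epoch
    pp_days = diagnosis_days + PREDICTION_POINT_OFFSET_DAYS

    op = spec.outcome_params
    lps = np.asarray(
        [_linear_predictor(b, op.coefficients) for b in baselines], dtype=float
    )
    base_total = op.base_hazard_infection + op.base_hazard_treatment
    p_infection = (
        op.base_hazard_infection / base_total if base_total > 0 else 0.5
    )
    rates = base_total * np.exp(lps)  # events / patient-year
    if op.target_2yr_rate is not None and base_total > 0:
        scale = _calibrate_scale(rates, 2.0, op.target_2yr_rate)
        rates = rates * scale

    with np.errstate(divide="ignore"):
        event_years = rng.exponential(1.0, size=n) / np.where(rates > 0, rates, np.inf)
    event_types = np.where(rng.random(n) < p_infection, "infection", "treatment")
    censor_days = rng.integers(op.censor_min_days, op.censor_max_days + 1, size=n)

    depths = rng.uniform(*spec.history_depth_years, size=n)

    records: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i:06d}"
        diag = int(diagnosis_days[i])
        pp = int(pp_days[i])
        fu_end = diag + int(censor_days[i])
        latent_day = (
            pp + int(round(event_years[i] * DAYS_PER_YEAR))
            if np.isfinite(event_years[i])
            else None
        )
        latent_type = str(event_types[i]) if latent_day is not None else "none"
        if latent_day is not None and latent_day <= fu_end:
            out_type, out_day = latent_type, latent_day
        else:
            out_type, out_day = "none", None

        # laboratory events over [pp - depth, min(pp or event, fu_end)]
        hist_start = pp - int(round(depths[i] * DAYS_PER_YEAR))
        obs_end = fu_end if out_day is None else min(out_day, fu_end)
        span_years = max(obs_end - hist_start, 0) / DAYS_PER_YEAR
        lab_events: list[tuple[str, int, float, str]] = []
        for lab in spec.lab_panel:
            k = rng.poisson(lab.per_year_rate * span_years)
            if k == 0:
                continue
            days = rng.integers(hist_start, obs_end + 1, size=k)
            values = rng.lognormal(lab.log_mean, lab.log_sd, size=k)
            for d, v in zip(days, values):
                lab_events.append((lab.name, int(d), float(v), lab.unit))
        lab_events.sort(key=lambda e: (e[0], e[1]))

        culture_start = max(hist_start, pp - int(round(spec.culture_history_years * DAYS_PER_YEAR)))
        culture_span = max(obs_end - culture_start, 0) / DAYS_PER_YEAR
        kc = rng.poisson(spec.culture_rate * culture_span)
        culture_events = sorted(
            int(d) for d in rng.integers(culture_start, obs_end + 1, size=kc)
        ) if kc > 0 else []

        records.append(
            PatientRecord(
                patient_id=pid,
                diagnosis_day=diag,
                baseline=baselines[i],
                lab_events=lab_events,
                culture_events=culture_events,
                outcome_type=out_type,
                outcome_day=out_day,
                followup_end_day=fu_end,
                latent_risk=float(lps[i]),
                latent_event_day=latent_day,
                latent_event_type=latent_type,
            )
        )

    if spec.missingness_profile:
        records = inject_missingness(records, spec.missingness_profile, seed=spec.seed + 1)
    return records


def inject_missingness(
    cohort: list[PatientRecord],
    profile: dict[str, float],
    seed: int = 0,
) -> list[PatientRecord]:
    """Independently blank values according to per-variable probabilities.

    Baseline variables are replaced by the explicit ``unknown`` category; a
    laboratory variable (or ``"cultures"``) is dropped wholesale for a patient
    with its probability. The input cohort is not modified.
    """
    if not cohort:
        return []
    baseline_vars = set(cohort[0].baseline)
    lab_vars = {e[0] for rec in cohort for e in rec.lab_events}
    known = baseline_vars | lab_vars | {"cultures"}
    for var, p in profile.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"probability for {var!r} is {p}, outside [0,1]")
        if var not in known:
            raise ConfigurationError(
                f"unknown variable {var!r}; known variables: {sorted(known)}"
            )

    rng = np.random.default_rng(seed)
    out: list[PatientRecord] = []
    for rec in cohort:
        baseline = dict(rec.baseline)
        for var in rec.baseline:
            p = profile.get(var, 0.0)
            if p > 0 and rng.random() < p:
                baseline[var] = UNKNOWN
        lab_events = rec.lab_events
        lab_profile = {v: profile[v] for v in profile if v in lab_vars}
        if lab_profile:
            dropped = {v for v, p in lab_profile.items() if p > 0 and rng.random() < p}
            if dropped:
                lab_events = [e for e in lab_events if e[0] not in dropped]
        culture_events = rec.culture_events
        pc = profile.get("cultures", 0.0)
        if pc > 0 and rng.random() < pc:
            culture_events = []
        out.append(
            dataclasses.replace(
                rec,
                baseline=baseline,
                lab_events=list(lab_events),
                culture_events=list(culture_events),
            )
        )
    return out


# --------------------------------------------------------------------------
# table export / import and source-dialect rendering
# --------------------------------------------------------------------------

def cohort_to_tables(cohort: list[PatientRecord]) -> dict[str, pd.DataFrame]:
    """Canonical long-format export (latent truth fields excluded)."""
    baseline_rows, lab_rows, culture_rows, outcome_rows = [], [], [], []
    for rec in cohort:
        for var, cat in sorted(rec.baseline.items()):
            baseline_rows.append((rec.patient_id, rec.diagnosis_day, var, cat))
        for var, day, value, unit in rec.lab_events:
            lab_rows.append((rec.patient_id, day, var, value, unit))
        for day in rec.culture_events:
            culture_rows.append((rec.patient_id, day))
        outcome_rows.append(
            (rec.patient_id, rec.outcome_type, rec.outcome_day, rec.followup_end_day)
        )
    return {
        "baseline": pd.DataFrame(
            baseline_rows, columns=["patient_id", "diagnosis_day", "variable", "category"]
        ),
        "labs": pd.DataFrame(
            lab_rows, columns=["patient_id", "day", "variable", "value", "unit"]
        ),
        "cultures": pd.DataFrame(culture_rows, columns=["patient_id", "day"]),
        "outcomes": pd.DataFrame(
            outcome_rows,
            columns=["patient_id", "event_type", "event_day", "followup_end_day"],
        ),
    }


def cohort_from_tables(tables: dict[str, pd.DataFrame]) -> list[PatientRecord]:
    """Rebuild patient records from canonical tables (inverse of export)."""
    baseline = tables["baseline"]
    labs = tables["labs"]
    cultures = tables["cultures"]
    outcomes = tables["outcomes"]

    recs: dict[str, PatientRecord] = {}
    for row in outcomes.itertuples(index=False):
        event_day = None if pd.isna(row.event_day) else int(row.event_day)
        recs[row.patient_id] = PatientRecord(
            patient_id=row.patient_id,
            diagnosis_day=0,
            baseline={},
            lab_events=[],
            culture_events=[],
            outcome_type=row.event_type,
            outcome_day=event_day,
            followup_end_day=int(row.followup_end_day),
        )
    for row in baseline.itertuples(index=False):
        rec = recs[row.patient_id]
        rec.diagnosis_day = int(row.diagnosis_day)
        rec.baseline[row.variable] = row.category
    for row in labs.itertuples(index=False):
        recs[row.patient_id].lab_events.append(
            (row.variable, int(row.day), float(row.value), row.unit)
        )
    for row in cultures.itertuples(index=False):
        recs[row.patient_id].culture_events.append(int(row.day))
    for rec in recs.values():
        rec.lab_events.sort(key=lambda e: (e[0], e[1]))
        rec.culture_events.sort()
    return [recs[pid] for pid in sorted(recs)]


def render_source(
    cohort: list[PatientRecord], dialect: SourceDialect
) -> dict[str, pd.DataFrame]:
    """Emit raw source tables in a dialect's labels and units.

    Lab values are transformed by the *inverse* of the unit map
    (``source = (canonical - offset) / factor``) so that harmonization with
    the matching dictionaries exactly recovers the canonical values. A
    corrupted entry applies a wrong (factor, offset) for that variable.
    """
    lab_vars = {e[0] for rec in cohort for e in rec.lab_events}
    for var in lab_vars:
        if var in dialect.unit_scramble:
            _, factor, _ = dialect.unit_scramble[var]
            if factor == 0:
                raise ConfigurationError(f"unit factor for {var!r} is zero")

    tables = cohort_to_tables(cohort)
    baseline = tables["baseline"].copy()
    baseline["variable"] = baseline["variable"].map(dialect.source_name)
    labs = tables["labs"].copy()
    new_values, new_units, new_vars = [], [], []
    for row in labs.itertuples(index=False):
        var = row.variable
        value = row.value
        unit = row.unit
        if var in dialect.unit_scramble:
            src_unit, factor, offset = dialect.unit_scramble[var]
            if var in dialect.corruption:
                factor, offset = dialect.corruption[var]
            value = (value - offset) / factor
            unit = src_unit
        new_values.append(value)
        new_units.append(unit)
        new_vars.append(dialect.source_name(var))
    labs["variable"] = new_vars
    labs["value"] = new_values
    labs["unit"] = new_units
    return {
        "baseline": baseline,
        "labs": labs,
        "cultures": tables["cultures"],
        "outcomes": tables["outcomes"],
    }


def write_cohort(cohort: list[PatientRecord], outdir: str | Path) -> dict[str, Path]:
    """Write the four canonical CSVs plus a generator-side truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = cohort_to_tables(cohort)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    truth = {
        rec.patient_id: {
            "latent_risk": rec.latent_risk,
            "latent_event_day": rec.latent_event_day,
            "latent_event_type": rec.latent_event_type,
        }
        for rec in cohort
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def composite_2yr_rate(cohort: list[PatientRecord], horizon_days: int = 730) -> float:
    """Ground-truth fraction with a composite event within the horizon.

    Uses the generator's uncensored latent event times, so the rate is the
    cohort's true underlying risk, unaffected by administrative censoring.
    """
    if not cohort:
        return float("nan")
    hits = sum(
        1
        for rec in cohort
        if rec.latent_event_day is not None
        and rec.latent_event_day - rec.prediction_point_day <= horizon_days
    )
    return hits / len(cohort)
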