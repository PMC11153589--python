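"""Heterogeneous feature-bagged ensemble with soft-vote confidence.

The prognostic committee is 28 base learners by default — 13 gradient-boosted
tree models (native missing-value handling), 7 random forests, 4 extremely
randomized trees, 2 elastic-net logistic and 2 plain logistic regressions —
of which 20 model the composite 2-year outcome, 5 the CLL-treatment outcome
and 3 the infection outcome. Each learner sees only its own random feature
bag, which decorrelates errors and makes the vote robust to unseen
missingness.

The model's *confidence* is the unweighted arithmetic mean of all learners'
positive-class probabilities (soft voting): 0 means confidently low-risk, 1
confidently high-risk, values near 0.5 mean disagreement. A patient is called
high-risk when confidence >= 0.5; confidence bands use cutoffs t_high = 0.58
and t_low = 0.28 by default (originally chosen so that ~20% of predictions are
high-risk high-confidence and ~30% low-risk high-confidence), with an optional
recalibrated t_high (e.g. 0.65).

Missingness policy per family: boosted trees consume NaN natively; forest and
linear families use median imputation fitted on training data only. A
prediction is produced for every patient regardless of missingness (100%
coverage contract).

Per-patient risk factors are obtained by feature occlusion: the contribution
of a feature is the confidence drop when that feature is replaced by its
missing representation, reusing the same missingness machinery the model is
built around; the top five positive and top five negative contributions are
reported.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from .features import FeatureMatrix, FeatureSpec
from .synth import ConfigurationError

__all__ = [
    "BaseLearnerSpec",
    "EnsembleConfig",
    "ConfidenceThresholds",
    "Prediction",
    "EnsembleModel",
    "train_ensemble",
    "predict",
    "derive_thresholds",
    "attribute_risk_factors",
    "default_thresholds",
    "save_model",
    "load_model",
]

FAMILIES = (
    "boosted_trees_native_missing",
    "random_forest",
    "extremely_randomized_trees",
    "elastic_net",
    "logistic",
)
OUTCOME_TARGETS = ("composite", "treatment", "infection")

_NATIVE_MISSING_FAMILIES = {"boosted_trees_native_missing"}


@dataclass(frozen=True)
class ConfidenceThresholds:
    t_high: float = 0.58
    t_low: float = 0.28

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_low < self.t_high <= 1.0:
            raise ConfigurationError(
                f"thresholds must satisfy 0 <= t_low < t_high <= 1, "
                f"got ({self.t_high}, {self.t_low})"
            )

    def band(self, confidence: float) -> str:
        if confidence >= self.t_high:
            return "high_conf_high_risk"
        if confidence <= self.t_low:
            return "high_conf_low_risk"
        return "low_confidence"


def default_thresholds() -> ConfidenceThresholds:
    """The packaged cutoffs (0.58, 0.28); no derivation involved."""
    return ConfidenceThresholds(0.58, 0.28)


@dataclass(frozen=True)
class BaseLearnerSpec:
    family: str
    outcome_target: str
    feature_bag: tuple[str, ...]
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown learner family {self.family!r}")
        if self.outcome_target not in OUTCOME_TARGETS:
            raise ConfigurationError(f"unknown outcome target {self.outcome_target!r}")
        if not self.feature_bag:
            raise ConfigurationError("feature bag must not be empty")

    @property
    def missing_policy(self) -> str:
        return "native" if self.family in _NATIVE_MISSING_FAMILIES else "median_impute"


# positions of the outcome-specific learners in the 28-learner sequence;
# interleaved so each family contributes to several targets
_TREATMENT_POSITIONS = (5, 10, 15, 20, 25)
_INFECTION_POSITIONS = (9, 18, 27)


@dataclass(frozen=True)
class EnsembleConfig:
    """Committee composition; defaults follow the 13/7/4/2/2 recipe."""

    n_boosted: int = 13
    n_random_forest: int = 7
    n_extra_trees: int = 4
    n_elastic_net: int = 2
    n_logistic: int = 2
    n_treatment: int = 5
    n_infection: int = 3
    bag_fraction: float = 0.5
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    @property
    def n_learners(self) -> int:
        return (self.n_boosted + self.n_random_forest + self.n_extra_trees
                + self.n_elastic_net + self.n_logistic)

    def validate(self) -> None:
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ConfigurationError("bag_fraction must be in (0, 1]")
        if self.n_treatment + self.n_infection > self.n_learners:
            raise ConfigurationError(
                "outcome-specific learner counts exceed the learner count"
            )

    def build_specs(self, feature_ids: list[str]) -> list[BaseLearnerSpec]:
        self.validate()
        families = (
            ["boosted_trees_native_missing"] * self.n_boosted
            + ["random_forest"] * self.n_random_forest
            + ["extremely_randomized_trees"] * self.n_extra_trees
            + ["elastic_net"] * self.n_elastic_net
            + ["logistic"] * self.n_logistic
        )
        n = len(families)
        targets = ["composite"] * n
        # spread outcome-specific learners across the family sequence
        treat_pos = [p for p in _TREATMENT_POSITIONS if p < n][: self.n_treatment]
        infect_pos = [p for p in _INFECTION_POSITIONS if p < n][: self.n_infection]
        free = [i for i in range(n) if i not in set(treat_pos) | set(infect_pos)]
        while len(treat_pos) < self.n_treatment:
            treat_pos.append(free.pop())
        while len(infect_pos) < self.n_infection:
            infect_pos.append(free.pop())
        for p in treat_pos:
            targets[p] = "treatment"
        for p in infect_pos:
            targets[p] = "infection"

        bag_size = max(1, round(self.bag_fraction * len(feature_ids)))
        specs = []
        for i, (family, target) in enumerate(zip(families, targets)):
            rng = np.random.default_rng(self.seed * 10_000 + i)
            bag = tuple(
                sorted(rng.choice(feature_ids, size=bag_size, replace=False))
            )
            specs.append(
                BaseLearnerSpec(
                    family=family,
                    outcome_target=target,
                    feature_bag=bag,
                    seed=self.seed * 10_000 + i,
                    hyperparameters=dict(self.hyperparameters.get(family, {})),
                )
            )
        return specs


@dataclass
class Prediction:
    patient_id: str
    confidence: float
    risk_call: str  # "high" | "low"
    band: str  # high_conf_high_risk | low_confidence | high_conf_low_risk
    risk_factors_up: list[tuple[str, float]] = field(default_factory=list)
    risk_factors_down: list[tuple[str, float]] = field(default_factory=list)


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def _make_estimator(spec: BaseLearnerSpec):
    hp = spec.hyperparameters
    if spec.family == "boosted_trees_native_missing":
        return XGBClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 3),
            learning_rate=hp.get("learning_rate", 0.2),
            tree_method="hist",
            n_jobs=1,
            random_state=spec.seed % (2**31),
            eval_metric="logloss",
            verbosity=0,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth", None),
            min_samples_leaf=hp.get("min_samples_leaf", 15),
            max_features=hp.get("max_features", 0.3),
            random_state=spec.seed % (2**31),
            n_jobs=1,
        )
    if spec.family == "extremely_randomized_trees":
        return ExtraTreesClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth", None),
            min_samples_leaf=hp.get("min_samples_leaf", 15),
            max_features=hp.get("max_features", 0.3),
            random_state=spec.seed % (2**31),
            n_jobs=1,
        )
    if spec.family == "elastic_net":
        return LogisticRegression(
            solver="saga",
            l1_ratio=hp.get("l1_ratio", 0.5),
            C=hp.get("C", 1.0),
            max_iter=hp.get("max_iter", 10000),
            tol=1e-3,
            random_state=spec.seed % (2**31),
        )
    return LogisticRegression(
        C=hp.get("C", 1.0), max_iter=hp.get("max_iter", 3000), solver="lbfgs"
    )


@dataclass
class FittedLearner:
    spec: BaseLearnerSpec
    estimator: object
    medians: np.ndarray | None  # imputation values, None for native policy
    scale: np.ndarray | None = None  # standardization for linear families
    center: np.ndarray | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.medians is not None:
            X = np.where(np.isnan(X), self.medians, X)
        if self.center is not None:
            X = X - self.center
        if self.scale is not None:
            X = X / self.scale
        return X

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        X = self._prepare(X)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]


@dataclass
class EnsembleModel:
    config: EnsembleConfig
    registry: list[FeatureSpec]
    learners: list[FittedLearner]

    @property
    def feature_ids(self) -> list[str]:
        return [s.feature_id for s in self.registry]

    def _check_columns(self, matrix: FeatureMatrix) -> pd.DataFrame:
        expected = self.feature_ids
        got = list(matrix.values.columns)
        if got != expected:
            unknown = sorted(set(got) - set(expected))
            missing = sorted(set(expected) - set(got))
            raise ConfigurationError(
                f"feature columns do not match the training registry "
                f"(unknown: {unknown[:5]}, missing: {missing[:5]})"
            )
        return matrix.values

    def confidence(self, matrix: FeatureMatrix) -> np.ndarray:
        """Soft vote: unweighted mean of per-learner positive probabilities."""
        values = self._check_columns(matrix)
        return self._confidence_array(values.to_numpy(dtype=float), values.columns)

    def _confidence_array(self, X: np.ndarray, columns) -> np.ndarray:
        col_index = {c: j for j, c in enumerate(columns)}
        total = np.zeros(X.shape[0])
        for learner in self.learners:
            idx = [col_index[f] for f in learner.spec.feature_bag]
            total += learner.predict_proba1(X[:, idx])
        return total / len(self.learners)


def train_ensemble(
    matrix: FeatureMatrix,
    labels: pd.DataFrame,
    config: EnsembleConfig | None = None,
) -> EnsembleModel:
    """Fit every base learner on its own feature bag.

    ``labels`` must hold one binary column per outcome target used by the
    configuration (``composite``, and ``treatment``/``infection`` when
    outcome-specific learners are configured), indexed like the matrix.
    """
    if config is None:
        config = EnsembleConfig()
    specs = config.build_specs([s.feature_id for s in matrix.registry])

    labels = labels.loc[matrix.values.index]
    for target in {s.outcome_target for s in specs}:
        if target not in labels.columns:
            raise ConfigurationError(f"labels are missing the {target!r} column")
        uniques = set(pd.unique(labels[target].dropna()))
        if not uniques >= {0, 1}:
            raise ConfigurationError(
                f"outcome target {target!r} has a single class in training data"
            )

    X_all = matrix.values.to_numpy(dtype=float)
    col_index = {c: j for j, c in enumerate(matrix.values.columns)}
    learners: list[FittedLearner] = []
    for spec in specs:
        idx = [col_index[f] for f in spec.feature_bag]
        X = X_all[:, idx]
        y = labels[spec.outcome_target].to_numpy(dtype=int)
        medians = None
        scale = None
        center = None
        if spec.missing_policy == "median_impute":
            medians = np.nanmedian(X, axis=0)
            medians = np.where(np.isnan(medians), 0.0, medians)
            X = np.where(np.isnan(X), medians, X)
        if spec.family in ("elastic_net", "logistic"):
            center = np.mean(X, axis=0)
            scale = np.std(X, axis=0)
            scale = np.where(scale <= 0, 1.0, scale)
            X = (X - center) / scale
        est = _make_estimator(spec)
        est.fit(X, y)
        learners.append(FittedLearner(spec, est, medians, scale, center))
    return EnsembleModel(config=config, registry=list(matrix.registry),
                         learners=learners)


def predict(
    model: EnsembleModel,
    matrix: FeatureMatrix,
    thresholds: ConfidenceThresholds | None = None,
    with_risk_factors: bool = False,
    top_k: int = 5,
) -> list[Prediction]:
    """Score every patient; never fails on missing values (full coverage)."""
    if thresholds is None:
        thresholds = default_thresholds()
    conf = model.confidence(matrix)
    preds = [
        Prediction(
            patient_id=pid,
            confidence=float(c),
            risk_call="high" if c >= 0.5 else "low",
            band=thresholds.band(float(c)),
        )
        for pid, c in zip(matrix.values.index, conf)
    ]
    if with_risk_factors:
        contrib = attribute_risk_factors(model, matrix)
        for pred in preds:
            up, down = top_risk_factors(contrib.loc[pred.patient_id], top_k)
            pred.risk_factors_up = up
            pred.risk_factors_down = down
    return preds


def predictions_frame(preds: list[Prediction]) -> pd.DataFrame:
    def fmt(factors):
        return ";".join(f"{f}:{c:.6g}" for f, c in factors)

    return pd.DataFrame(
        [
            (p.patient_id, p.confidence, p.risk_call, p.band,
             fmt(p.risk_factors_up), fmt(p.risk_factors_down))
            for p in preds
        ],
        columns=["patient_id", "confidence", "risk_call", "band",
                 "risk_factors_up", "risk_factors_down"],
    )


def derive_thresholds(
    confidences, frac_high: float = 0.20, frac_low: float = 0.30
) -> ConfidenceThresholds:
    """Empirical-quantile cutoffs achieving the requested band fractions.

    ``t_high`` is the smallest observed confidence such that the fraction of
    confidences >= t_high is <= frac_high; ``t_low`` analogously from below.
    The packaged defaults (0.58, 0.28) bypass this derivation entirely.
    """
    conf = np.sort(np.asarray(list(confidences), dtype=float))
    n = len(conf)
    if n < 10:
        raise ConfigurationError("need at least 10 confidences to derive thresholds")
    if not (0.0 < frac_high + frac_low <= 1.0):
        raise ConfigurationError("fractions must satisfy 0 < frac_high + frac_low <= 1")
    i = next(i for i in range(n) if (n - i) / n <= frac_high)
    t_high = float(conf[i])
    j = max((j for j in range(n) if (j + 1) / n <= frac_low), default=None)
    t_low = float(conf[j]) if j is not None else max(0.0, float(conf[0]) - 1e-9)
    if t_low >= t_high:
        t_low = np.nextafter(t_high, -np.inf)
    return ConfidenceThresholds(t_high=t_high, t_low=t_low)


# --------------------------------------------------------------------------
# risk-factor attribution (occlusion to the missing representation)
# --------------------------------------------------------------------------

def attribute_risk_factors(
    model: EnsembleModel, matrix: FeatureMatrix
) -> pd.DataFrame:
    """Signed per-feature contributions for every patient (patients x features).

    contribution(f) = confidence(row) - confidence(row with f occluded to its
    missing representation); positive values push towards high risk.
    """
    values = model._check_columns(matrix)
    X = values.to_numpy(dtype=float)
    out = np.zeros_like(X)
    feature_users = {
        fid: [lr for lr in model.learners if fid in set(lr.spec.feature_bag)]
        for fid in model.feature_ids
    }
    col_index = {c: j for j, c in enumerate(values.columns)}
    n_learners = len(model.learners)
    # per-learner cached probabilities so occlusion re-scores only the users
    cached = np.stack(
        [
            lr.predict_proba1(X[:, [col_index[f] for f in lr.spec.feature_bag]])
            for lr in model.learners
        ]
    )
    learner_pos = {id(lr): k for k, lr in enumerate(model.learners)}
    for spec in model.registry:
        users = feature_users[spec.feature_id]
        if not users:
            continue
        j = col_index[spec.feature_id]
        X_occ = X.copy()
        X_occ[:, j] = spec.missing_representation
        delta = np.zeros(X.shape[0])
        for lr in users:
            idx = [col_index[f] for f in lr.spec.feature_bag]
            new = lr.predict_proba1(X_occ[:, idx])
            delta += cached[learner_pos[id(lr)]] - new
        out[:, j] = delta / n_learners
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def top_risk_factors(
    contributions: pd.Series, k: int = 5
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top-k positive and top-k negative contributions.

    Sorted by absolute contribution descending; exact ties broken by
    feature id so the ranking is deterministic.
    """
    items = [(fid, float(c)) for fid, c in contributions.items() if c != 0.0]
    up = sorted((x for x in items if x[1] > 0), key=lambda x: (-abs(x[1]), x[0]))[:k]
    down = sorted((x for x in items if x[1] < 0), key=lambda x: (-abs(x[1]), x[0]))[:k]
    return up, down


# --------------------------------------------------------------------------
# serialization: one zip archive (JSON manifest + per-learner joblib blobs)
# --------------------------------------------------------------------------

_ZIP_DATE = (2020, 1, 1, 0, 0, 0)  # fixed timestamp => byte-stable archives


def save_model(model: EnsembleModel, path: str | Path) -> None:
    path = Path(path)
    manifest = {
        "config": {
            k: v for k, v in model.config.__dict__.items() if k != "hyperparameters"
        },
        "hyperparameters": model.config.hyperparameters,
        "registry": [
            [s.feature_id, s.variable, s.window_days, s.aggregator, s.applies_to,
             s.level]
            for s in model.registry
        ],
        "learners": [
            {
                "family": lr.spec.family,
                "outcome_target": lr.spec.outcome_target,
                "seed": lr.spec.seed,
                "n_bag": len(lr.spec.feature_bag),
            }
            for lr in model.learners
        ],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("manifest.json", date_time=_ZIP_DATE)
        zf.writestr(info, json.dumps(manifest, indent=1, sort_keys=True))
        for i, lr in enumerate(model.learners):
            buf = io.BytesIO()
            joblib.dump(lr, buf)
            info = zipfile.ZipInfo(f"learners/{i:03d}.joblib", date_time=_ZIP_DATE)
            zf.writestr(info, buf.getvalue())
        buf = io.BytesIO()
        joblib.dump((model.config, model.registry), buf)
        info = zipfile.ZipInfo("model_meta.joblib", date_time=_ZIP_DATE)
        zf.writestr(info, buf.getvalue())


def load_model(path: str | Path) -> EnsembleModel:
    with zipfile.ZipFile(path) as zf:
        config, registry = joblib.load(io.BytesIO(zf.read("model_meta.joblib")))
        names = sorted(
            n for n in zf.namelist() if n.startswith("learners/")
        )
        learners = [joblib.load(io.BytesIO(zf.read(n))) for n in names]
    return EnsembleModel(config=config, registry=registry, learners=learners)
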