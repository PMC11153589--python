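"""Quarterly drift monitoring: data shifts and performance decay.

Deployed prognostic models degrade silently: the input distributions drift
(new instruments, new coding practice, new patient mix) long before enough
2-year outcomes mature to measure a performance drop directly. The monitor
therefore watches both channels every window (default 91 days ~ quarterly):

* data shift — every numeric model input is compared to a reference
  (training-era) snapshot with a population-stability index (PSI) over
  reference deciles plus a two-sample Kolmogorov-Smirnov test; categorical
  inputs and the confidence distribution use PSI over categories. A variable
  is flagged when PSI exceeds its threshold (default 0.2, the conventional
  "significant shift" cut) or the KS test rejects at the Bonferroni-adjusted
  level (default family alpha 0.01).
* performance decay — MCC / precision / recall computed only on patients
  whose 2-year horizon has matured inside the window, compared to reference
  performance with a configurable drop margin.

The report's alarm is raised iff any variable is flagged or any matured
metric drops beyond its margin; it is a pure function of (reference,
current, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .evaluation import ConfusionMatrix, classification_metrics
from .synth import ConfigurationError

__all__ = [
    "DriftConfig",
    "MonitoringWindow",
    "DriftReport",
    "psi_numeric",
    "psi_categorical",
    "evaluate_window",
    "schedule_windows",
]

_PSEUDO_COUNT = 0.5  # guard against empty bins keeping PSI finite


def psi_numeric(reference, current, bins: int = 10) -> float:
    """Population-stability index over reference-decile bins.

    Nonnegative and zero iff the binned distributions are identical.
    """
    ref = np.asarray(reference, dtype=float)
    cur = np.asarray(current, dtype=float)
    ref = ref[~np.isnan(ref)]
    cur = cur[~np.isnan(cur)]
    if len(ref) == 0 or len(cur) == 0:
        return float("nan")
    edges = np.unique(np.quantile(ref, np.linspace(0, 1, bins + 1)))
    if len(edges) < 2:
        edges = np.asarray([edges[0] - 0.5, edges[0] + 0.5])
    edges[0], edges[-1] = -np.inf, np.inf
    ref_counts = np.histogram(ref, edges)[0] + _PSEUDO_COUNT
    cur_counts = np.histogram(cur, edges)[0] + _PSEUDO_COUNT
    p = ref_counts / ref_counts.sum()
    q = cur_counts / cur_counts.sum()
    return float(np.sum((p - q) * np.log(p / q)))


def psi_categorical(reference, current) -> float:
    ref = pd.Series(list(reference))
    cur = pd.Series(list(current))
    cats = sorted(set(ref.unique()) | set(cur.unique()))
    ref_counts = ref.value_counts().reindex(cats).fillna(0).to_numpy() + _PSEUDO_COUNT
    cur_counts = cur.value_counts().reindex(cats).fillna(0).to_numpy() + _PSEUDO_COUNT
    p = ref_counts / ref_counts.sum()
    q = cur_counts / cur_counts.sum()
    return float(np.sum((p - q) * np.log(p / q)))


@dataclass(frozen=True)
class DriftConfig:
    psi_threshold: float = 0.2
    ks_alpha: float = 0.01  # family-wise, Bonferroni-split across variables
    performance_margin: float = 0.15  # tolerated absolute metric drop
    bins: int = 10


@dataclass
class WindowData:
    """Inputs and outputs of the model inside one time window."""

    features: pd.DataFrame  # numeric model inputs (patients x variables)
    confidences: np.ndarray | None = None
    categoricals: pd.DataFrame | None = None
    matured: pd.DataFrame | None = None  # columns: y_true (0/1), y_pred (0/1)


@dataclass
class MonitoringWindow:
    start_day: int
    end_day: int  # exclusive
    partial: bool  # True when the window is not the standard length
    log: pd.DataFrame  # rows of the prediction log falling in the window

    def matured_in_window(
        self, predictions_log: pd.DataFrame, horizon_days: int = 730
    ) -> pd.DataFrame:
        """Rows of the full log whose outcome matures inside this window.

        A prediction matures on ``prediction_day + horizon`` provided the
        patient's follow-up covers the horizon.
        """
        maturity = predictions_log["prediction_day"] + horizon_days
        covered = (
            predictions_log["followup_end_day"] - predictions_log["prediction_day"]
        ) >= horizon_days
        mask = covered & (maturity >= self.start_day) & (maturity < self.end_day)
        return predictions_log[mask]


@dataclass
class DriftReport:
    variable_stats: pd.DataFrame  # variable, kind, psi, ks_p, flagged
    confidence_psi: float | None
    confidence_flagged: bool
    performance: dict
    alarm: bool

    def to_dict(self) -> dict:
        return {
            "variables": self.variable_stats.to_dict(orient="records"),
            "confidence_psi": self.confidence_psi,
            "confidence_flagged": self.confidence_flagged,
            "performance": self.performance,
            "alarm": self.alarm,
        }

    def to_markdown(self) -> str:
        lines = ["# Drift report", ""]
        lines.append(f"Alarm: {'YES' if self.alarm else 'no'}")
        flagged = self.variable_stats[self.variable_stats["flagged"]]
        lines.append(f"Flagged variables: {', '.join(flagged['variable']) or 'none'}")
        if self.confidence_psi is not None:
            lines.append(f"Confidence PSI: {self.confidence_psi:.4f}"
                         f" ({'flagged' if self.confidence_flagged else 'ok'})")
        perf = self.performance
        lines.append(f"Performance: {perf.get('status', 'n/a')}")
        return "\n".join(lines)


def evaluate_window(
    reference: WindowData,
    current: WindowData,
    config: DriftConfig | None = None,
) -> DriftReport:
    """Compare one monitoring window against the reference snapshot."""
    if config is None:
        config = DriftConfig()
    if reference.features.empty or current.features.empty:
        raise ConfigurationError("reference and current windows must be nonempty")

    numeric_vars = [c for c in reference.features.columns
                    if c in current.features.columns]
    cat_vars = []
    if reference.categoricals is not None and current.categoricals is not None:
        cat_vars = [c for c in reference.categoricals.columns
                    if c in current.categoricals.columns]
    n_tests = len(numeric_vars) + len(cat_vars)
    ks_cut = config.ks_alpha / max(n_tests, 1)  # Bonferroni

    rows = []
    for var in numeric_vars:
        ref = reference.features[var].to_numpy(dtype=float)
        cur = current.features[var].to_numpy(dtype=float)
        psi = psi_numeric(ref, cur, config.bins)
        ref_c = ref[~np.isnan(ref)]
        cur_c = cur[~np.isnan(cur)]
        if len(ref_c) and len(cur_c):
            ks_p = float(ks_2samp(ref_c, cur_c).pvalue)
        else:
            ks_p = float("nan")
        flagged = (not np.isnan(psi) and psi > config.psi_threshold) or (
            not np.isnan(ks_p) and ks_p < ks_cut
        )
        rows.append((var, "numeric", psi, ks_p, flagged))
    for var in cat_vars:
        psi = psi_categorical(reference.categoricals[var],
                              current.categoricals[var])
        flagged = psi > config.psi_threshold
        rows.append((var, "categorical", psi, float("nan"), flagged))
    variable_stats = pd.DataFrame(
        rows, columns=["variable", "kind", "psi", "ks_p", "flagged"]
    )

    confidence_psi = None
    confidence_flagged = False
    if reference.confidences is not None and current.confidences is not None:
        confidence_psi = psi_numeric(reference.confidences,
                                     current.confidences, config.bins)
        confidence_flagged = confidence_psi > config.psi_threshold

    performance: dict = {"status": "immature"}
    perf_alarm = False
    if current.matured is not None and len(current.matured) > 0:
        cur_metrics = _performance(current.matured)
        performance = {"status": "evaluated", "current": cur_metrics,
                       "n_matured": int(len(current.matured))}
        if reference.matured is not None and len(reference.matured) > 0:
            ref_metrics = _performance(reference.matured)
            performance["reference"] = ref_metrics
            drops = {}
            for m in ("MCC", "precision", "recall"):
                if cur_metrics.get(m) is not None and ref_metrics.get(m) is not None:
                    drops[m] = ref_metrics[m] - cur_metrics[m]
            performance["drops"] = drops
            perf_alarm = any(d > config.performance_margin for d in drops.values())

    alarm = bool(variable_stats["flagged"].any()) or confidence_flagged or perf_alarm
    return DriftReport(
        variable_stats=variable_stats,
        confidence_psi=confidence_psi,
        confidence_flagged=confidence_flagged,
        performance=performance,
        alarm=alarm,
    )


def _performance(matured: pd.DataFrame) -> dict:
    y = matured["y_true"].to_numpy(dtype=int)
    yhat = matured["y_pred"].to_numpy(dtype=int)
    cm = ConfusionMatrix(
        tp=int(np.sum((yhat == 1) & (y == 1))),
        fp=int(np.sum((yhat == 1) & (y == 0))),
        tn=int(np.sum((yhat == 0) & (y == 0))),
        fn=int(np.sum((yhat == 0) & (y == 1))),
    )
    return classification_metrics(cm)


def schedule_windows(
    predictions_log: pd.DataFrame, window_days: int = 91
) -> list[MonitoringWindow]:
    """Partition a timestamped prediction log into consecutive windows.

    The log needs a ``prediction_day`` column (integer day); the final
    window is flagged partial when the log does not fill it. Patients
    mature — for the performance section — once their follow-up covers the
    730-day horizon (see :meth:`MonitoringWindow.matured_mask`).
    """
    if predictions_log.empty:
        return []
    if window_days <= 0:
        raise ConfigurationError("window_days must be positive")
    days = predictions_log["prediction_day"]
    start = int(days.min())
    span = int(days.max()) - start + 1
    # remainder days fold into the final window, which is flagged partial
    n_windows = max(1, span // window_days)
    partial_last = span % window_days != 0
    windows = []
    for k in range(n_windows):
        w_start = start + k * window_days
        last = k == n_windows - 1
        w_end = start + span if last else w_start + window_days
        mask = (days >= w_start) & (days < w_end)
        windows.append(
            MonitoringWindow(
                start_day=w_start,
                end_day=w_end,
                partial=last and partial_last,
                log=predictions_log[mask].copy(),
            )
        )
    return windows
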