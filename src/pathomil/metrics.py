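"""Evaluation statistics: discrimination, survival, stratification, baselines.

Implements the evaluation toolkit around the MIL models: ROC-AUC with
bootstrap CIs, threshold metrics, Harrell's C-index, IPCW time-dependent AUC,
Kaplan–Meier estimation with Greenwood log-log intervals, tertile risk-group
stratification with frozen training cutpoints, Pearson chi-square and
Kruskal–Wallis baseline tests, paired bootstrap metric comparison, and the
multi-seed trial summary (mean ± 1.96·sd/√n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.metrics import roc_auc_score

from .losses import SurvivalLabel

__all__ = [
    "MetricSummary",
    "ContingencyTable",
    "RiskGroupThresholds",
    "KMCurve",
    "roc_auc",
    "threshold_metrics",
    "harrell_c",
    "time_dependent_auc",
    "km_estimate",
    "tertile_stratify",
    "assign_risk_groups",
    "chi_square_independence",
    "kruskal_wallis",
    "bootstrap_compare",
    "trials_summary",
]

RISK_GROUPS = ("low", "intermediate", "high")


@dataclass
class MetricSummary:
    point: float
    ci_low: float
    ci_high: float
    n: int = 0

    def __post_init__(self):
        if not (self.ci_low <= self.point <= self.ci_high):
            # guard against degenerate bootstrap ordering from float noise
            self.ci_low = min(self.ci_low, self.point)
            self.ci_high = max(self.ci_high, self.point)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.point, self.ci_low, self.ci_high)


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2×2")
        if (self.counts < 0).any() or self.counts.sum() == 0:
            raise ValueError("counts must be non-negative with positive total")


@dataclass
class RiskGroupThresholds:
    q1: float
    q2: float

    def __post_init__(self):
        if self.q1 > self.q2:
            raise ValueError("q1 must not exceed q2")

    def assign(self, score: float) -> str:
        if score <= self.q1:
            return "low"
        if score <= self.q2:
            return "intermediate"
        return "high"


@dataclass
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censor_times: np.ndarray
    median: float  # np.inf when not reached
    median_ci: tuple[float, float] = (np.nan, np.nan)

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _split_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([lab.time for lab in labels], dtype=np.float64)
    events = np.array([lab.event for lab in labels], dtype=np.int64)
    return times, events


def roc_auc(
    scores, labels, n_boot: int = 1000, seed: int = 0, ci: bool = True
) -> MetricSummary:
    """Rank-based AUC (ties count 1/2) with a patient-level bootstrap CI."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    point = float(roc_auc_score(labels, scores))
    if not ci:
        return MetricSummary(point, point, point, n=len(scores))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(scores)
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MetricSummary(point, float(lo), float(hi), n=n)


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Precision/recall/F1/specificity at ``score > threshold`` (class 1 +ve)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0:
        raise ValueError("empty input")
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": specificity,
    }


def harrell_c(
    risks, labels, n_boot: int = 0, seed: int = 0
) -> MetricSummary:
    """Harrell's concordance: higher risk should pair with shorter survival."""
    risks = np.asarray(risks, dtype=np.float64)
    times, events = _split_labels(labels)
    if events.sum() == 0:
        raise ValueError("C-index undefined: no comparable pairs")
    point = float(concordance_index(times, -risks, events))
    if n_boot <= 0:
        return MetricSummary(point, point, point, n=len(risks))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(risks)
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        if events[idx].sum() == 0:
            continue
        boots.append(concordance_index(times[idx], -risks[idx], events[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MetricSummary(point, float(lo), float(hi), n=n)


def time_dependent_auc(risks, labels, horizon: float) -> MetricSummary:
    """Cumulative/dynamic AUC at the horizon with IPCW censoring weights."""
    from sksurv.metrics import cumulative_dynamic_auc

    risks = np.asarray(risks, dtype=np.float64)
    times, events = _split_labels(labels)
    if events[times <= horizon].sum() == 0:
        raise ValueError(f"time-dependent AUC undefined: no events by t={horizon}")
    if (times > horizon).sum() == 0:
        raise ValueError(f"time-dependent AUC undefined: nobody at risk past t={horizon}")
    y = np.array(
        [(bool(e), t) for e, t in zip(events, times)],
        dtype=[("event", "?"), ("time", "<f8")],
    )
    auc, _ = cumulative_dynamic_auc(y, y, risks, np.array([horizon]))
    return MetricSummary(float(auc[0]), float(auc[0]), float(auc[0]), n=len(risks))


def km_estimate(labels, horizons=()) -> tuple[KMCurve, dict[float, MetricSummary]]:
    """Product-limit estimate with Greenwood log-log CIs.

    Returns the curve (with median; ``inf`` = not reached) and, for each
    requested horizon, Ŝ(t) with its 95% CI.
    """
    times, events = _split_labels(labels)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_["KM_estimate"]
    timeline = sf.index.to_numpy(dtype=np.float64)
    keep = timeline > 0
    event_times = timeline[keep]
    survival = sf.to_numpy()[keep]
    et = kmf.event_table
    at_risk = et["at_risk"].reindex(event_times).to_numpy()
    observed = et["observed"].reindex(event_times).to_numpy()
    median = float(kmf.median_survival_time_)
    from lifelines.utils import median_survival_times

    ci_df = median_survival_times(kmf.confidence_interval_)
    median_ci = (float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1]))
    curve = KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        events=observed,
        censor_times=times[events == 0],
        median=median,
        median_ci=median_ci,
    )
    horizon_estimates: dict[float, MetricSummary] = {}
    ci_band = kmf.confidence_interval_
    for t in horizons:
        s = float(kmf.survival_function_at_times(t).iloc[0])
        idx = ci_band.index.to_numpy()
        pos = np.searchsorted(idx, t, side="right") - 1
        pos = max(pos, 0)
        lo = float(ci_band.iloc[pos, 0])
        hi = float(ci_band.iloc[pos, 1])
        horizon_estimates[t] = MetricSummary(s, lo, hi, n=len(times))
    return curve, horizon_estimates


def tertile_stratify(train_scores) -> RiskGroupThresholds:
    """Tertile cutpoints (1/3 and 2/3 linear-interpolation quantiles).

    Thresholds are derived from training risk scores once and applied frozen
    to validation/test scores.
    """
    scores = np.asarray(train_scores, dtype=np.float64)
    if len(np.unique(scores)) < 3:
        raise ValueError("degenerate stratification: need >= 3 distinct scores")
    q1, q2 = np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0])
    return RiskGroupThresholds(q1=float(q1), q2=float(q2))


def assign_risk_groups(scores, thresholds: RiskGroupThresholds) -> list[str]:
    return [thresholds.assign(float(s)) for s in np.asarray(scores).ravel()]


def chi_square_independence(table: ContingencyTable | np.ndarray):
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = table.counts if isinstance(table, ContingencyTable) else \
        ContingencyTable(np.asarray(table)).counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) with chi-square p on k−1 df."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; zero variance", RuntimeWarning)
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bootstrap_compare(
    metric, predictions_a, predictions_b, targets,
    n_boot: int = 1000, seed: int = 0,
) -> dict:
    """Paired bootstrap test of metric(A) − metric(B) on the same patients.

    ``metric(scores, targets_resampled)`` is called on each resample; invalid
    resamples (metric raises) are redrawn, capped at 10% of ``n_boot``.
    Returns the observed delta, percentile 95% CI and a two-sided p-value
    2·min(P(Δ*≤0), P(Δ*≥0)) capped at 1.
    """
    a = np.asarray(predictions_a, dtype=np.float64)
    b = np.asarray(predictions_b, dtype=np.float64)
    targets = np.asarray(targets)
    if a.shape != b.shape or a.shape[0] != targets.shape[0]:
        raise ValueError("paired predictions must align with targets")
    delta_obs = float(metric(a, targets) - metric(b, targets))
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    deltas: list[float] = []
    redraws = 0
    max_redraws = max(1, n_boot // 10)
    while len(deltas) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            deltas.append(float(metric(a[idx], targets[idx]) -
                                metric(b[idx], targets[idx])))
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    "bootstrap: too many invalid resamples (>10%)"
                ) from None
    deltas_arr = np.array(deltas)
    lo, hi = np.percentile(deltas_arr, [2.5, 97.5])
    p_le = float(np.mean(deltas_arr <= 0))
    p_ge = float(np.mean(deltas_arr >= 0))
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return {
        "delta": delta_obs,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_value": p,
        "n_boot": n_boot,
        "redraws": redraws,
    }


def trials_summary(metric_values) -> MetricSummary:
    """Mean ± 1.96·sd/√n across independent trials."""
    values = np.asarray(metric_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need >= 2 trial values")
    mean = float(values.mean())
    half = 1.96 * float(values.std(ddof=1)) / np.sqrt(values.size)
    return MetricSummary(mean, mean - half, mean + half, n=values.size)


def make_survival_labels(times, events) -> list[SurvivalLabel]:
    return [SurvivalLabel(float(t), int(e)) for t, e in zip(times, events)]
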