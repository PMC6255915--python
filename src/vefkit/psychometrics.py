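"""Psychometric curves, criterion calibration, sigmoid fits, thresholds.

The discrimination threshold of an animal is the orientation difference at
which a logistic fit of a performance metric versus ΔOri,

    f(ΔOri) = L / (1 + exp(-s (ΔOri - o))),

crosses a criterion value calibrated to lie just above chance.  Hit index
and PR score increase with performance; target distance decreases, so its
curve is fitted on the performance-increasing transform ``chance - value``
and its criterion is transformed the same way, letting one threshold
routine serve all three metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import Geometry, MetricParams
from .errors import FitError, UndefinedMetricError, ValidationError
from .metrics import path_reliability
from .session_io import TrialSlice

#: metric -> (direction, chance level); criteria below are on the raw scale.
#: Fits operate on the performance-increasing, chance-floored transform
#: (value - chance, or chance - value for decreasing metrics) so the
#: logistic's zero floor matches each metric's chance level (hit index 0,
#: target distance 1, PR score ~1).
POLARITY = {
    "hit_index": ("increasing", 0.0),
    "target_distance": ("decreasing", 1.0),
    "pr_score": ("increasing", 1.0),
}

#: conventional criteria (chance shifted by the pooled-median bootstrap SEM)
DEFAULT_CRITERIA = {"hit_index": 0.2, "target_distance": 0.82, "pr_score": 1.25}

THRESHOLD_METRICS = ("hit_index", "target_distance", "pr_score")


@dataclass
class PsychometricCurve:
    metric_name: str
    delta_ori: np.ndarray  # ascending
    mean_value: np.ndarray
    n: np.ndarray
    sem: np.ndarray | None = None  # per-level uncertainty, used as fit weights
    omitted_levels: list[float] = field(default_factory=list)


@dataclass
class SigmoidFit:
    L: float
    s: float
    o: float
    residual_norm: float
    chance: float = 0.0   # chance level subtracted before fitting
    flipped: bool = False  # fitted on (chance - value) for decreasing metrics

    def transform(self, value: np.ndarray | float):
        """Raw metric value -> performance-increasing fitted scale."""
        return self.chance - value if self.flipped else value - self.chance

    def predict(self, delta_ori: np.ndarray) -> np.ndarray:
        """Fitted curve on the metric's raw scale."""
        y = logistic(np.asarray(delta_ori, dtype=float), self.L, self.s, self.o)
        return self.chance - y if self.flipped else y + self.chance


@dataclass
class CriterionSet:
    metric_name: str
    chance_level: float
    median_sem: float
    criterion: float
    fractions: tuple[float, ...]
    reps: int
    n_sems: int


@dataclass
class ThresholdEstimate:
    condition: str
    per_metric: dict  # metric -> threshold (deg) or None for not-reached
    averaged: float | None
    n_trials: int


def logistic(x: np.ndarray, L: float, s: float, o: float) -> np.ndarray:
    return L / (1.0 + np.exp(-s * (x - o)))


# ---------------------------------------------------------------------------
# Curves


def build_curve(
    table: pd.DataFrame,
    metric_name: str,
    mask: np.ndarray | None = None,
    slices: list[TrialSlice] | None = None,
    geometry: Geometry | None = None,
    params: MetricParams | None = None,
) -> PsychometricCurve:
    """Per-ΔOri mean of a metric over masked, included choice trials.

    For ``pr_score`` the value per level is the PR score of that level's
    trial set (a set statistic), which requires the trial ``slices``; for
    the per-trial metrics only the metric table is needed.  Levels with no
    trials (or an undefined set statistic) are omitted and recorded.
    """
    sel = table["include_flag"].to_numpy().copy()
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    sub = table[sel]
    if sub.empty:
        raise UndefinedMetricError("no included trials under the given mask")
    levels = np.array(sorted(sub["delta_ori"].dropna().unique()))
    means, ns, sems, omitted = [], [], [], []
    if metric_name == "pr_score":
        if slices is None:
            raise ValidationError("pr_score curves require the trial slices")
        by_id = {s.trial_id: s for s in slices}
        for lv in levels:
            ids = sub.loc[sub["delta_ori"] == lv, "trial_id"]
            trial_set = [by_id[i] for i in ids if i in by_id]
            res = path_reliability(trial_set, geometry or Geometry(), params or MetricParams())
            if res is None:
                omitted.append(float(lv))
            else:
                means.append(res.pr_score)
                ns.append(len(trial_set))
                # large-sample SD of a Cohen's d estimate
                n_l, n_r = max(res.n_left, 2), max(res.n_right, 2)
                d = res.pr_score
                sems.append(float(np.sqrt(
                    1.0 / n_l + 1.0 / n_r + d**2 / (2.0 * (n_l + n_r - 2))
                )))
    else:
        if metric_name not in sub.columns:
            raise ValidationError(f"unknown metric {metric_name!r}")
        for lv in levels:
            vals = sub.loc[sub["delta_ori"] == lv, metric_name].dropna()
            if len(vals) == 0:
                omitted.append(float(lv))
            else:
                means.append(float(vals.mean()))
                ns.append(len(vals))
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                sems.append(sd / np.sqrt(len(vals)))
    kept = [lv for lv in levels if lv not in omitted]
    return PsychometricCurve(
        metric_name=metric_name,
        delta_ori=np.asarray(kept, dtype=float),
        mean_value=np.asarray(means, dtype=float),
        n=np.asarray(ns, dtype=int),
        sem=np.asarray(sems, dtype=float),
        omitted_levels=omitted,
    )


# ---------------------------------------------------------------------------
# Bootstrap criterion calibration


def bootstrap_criterion(
    tables: list[pd.DataFrame],
    metric_name: str,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    reps: int = 10,
    seed: int | np.random.Generator = 0,
    chance_level: float | None = None,
) -> CriterionSet:
    """Criterion = chance shifted towards performance by the pooled-median SEM.

    For every animal, ΔOri level, trial fraction and repetition, a subset of
    trials is sampled without replacement and its SEM = SD/sqrt(n) recorded;
    the criterion shifts chance by the median of the pooled SEM distribution
    (upwards for performance-increasing metrics, downwards for target
    distance).  Subsets with fewer than two trials are skipped.
    """
    if metric_name not in POLARITY:
        raise ValidationError(f"unknown metric {metric_name!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    direction, default_chance = POLARITY[metric_name]
    chance = default_chance if chance_level is None else chance_level
    # the PR score is a set statistic; its per-trial substrate is local PR
    column = "local_pr" if metric_name == "pr_score" else metric_name
    sems = []
    for table in tables:
        sub = table[table["include_flag"]]
        for lv in sorted(sub["delta_ori"].dropna().unique()):
            vals = sub.loc[sub["delta_ori"] == lv, column].dropna().to_numpy()
            for frac in fractions:
                k = int(round(frac * len(vals)))
                if k < 2:
                    continue
                for _ in range(reps):
                    sample = rng.choice(vals, size=k, replace=False)
                    sems.append(sample.std(ddof=1) / np.sqrt(k))
    if not sems:
        raise UndefinedMetricError("no subsets with >= 2 trials; cannot calibrate")
    med = float(np.median(sems))
    crit = chance + med if direction == "increasing" else chance - med
    return CriterionSet(
        metric_name=metric_name, chance_level=chance, median_sem=med,
        criterion=crit, fractions=tuple(fractions), reps=reps, n_sems=len(sems),
    )


def calibrate_criteria(
    tables: list[pd.DataFrame],
    chance_levels: dict[str, float] | None = None,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    reps: int = 10,
    seed: int | np.random.Generator = 0,
    metrics: tuple[str, ...] = THRESHOLD_METRICS,
) -> dict[str, float]:
    """Bootstrap-calibrated criteria for a cohort of metric tables.

    Runs :func:`bootstrap_criterion` per metric and returns the criterion
    values keyed by metric, optionally overriding the default chance
    levels (e.g. with a simulator's analytic chance target distance).
    """
    chance_levels = chance_levels or {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {
        m: bootstrap_criterion(
            tables, m, fractions=fractions, reps=reps, seed=rng,
            chance_level=chance_levels.get(m),
        ).criterion
        for m in metrics
    }


# ---------------------------------------------------------------------------
# Sigmoid fit and threshold


def fit_sigmoid(curve: PsychometricCurve) -> SigmoidFit:
    """Least-squares logistic fit on the performance-increasing scale."""
    if len(curve.delta_ori) < 4:
        raise FitError(
            f"{curve.metric_name}: need >= 4 populated levels, got {len(curve.delta_ori)}"
        )
    direction, chance = POLARITY.get(curve.metric_name, ("increasing", 0.0))
    x = curve.delta_ori
    y = curve.mean_value.astype(float)
    flipped = direction == "decreasing"
    y = chance - y if flipped else y - chance
    rng_y = max(float(y.max() - min(y.min(), 0.0)), 1e-6)
    L0 = max(float(y.max()), 1e-3)
    o0 = float(x[np.argmin(np.abs(y - y.max() / 2.0))])
    bounds = ([1e-6, 1e-6, 0.0], [2.0 * rng_y + 1.0, 5.0, 90.0])
    sigma = None
    if curve.sem is not None and np.all(np.isfinite(curve.sem)):
        floor = max(1e-3, 0.05 * float(np.median(curve.sem[curve.sem > 0])
                                       if (curve.sem > 0).any() else 1.0))
        sigma = np.maximum(curve.sem, floor)
    # deterministic multi-start over slope/offset inits; keep the best
    # weighted least-squares solution
    best, best_cost = None, np.inf
    o_inits = {o0, float(np.median(x))}
    for s0 in (0.05, 0.1, 0.2, 0.4, 0.8, 1.6):
        for o_init in sorted(o_inits):
            try:
                popt, _ = curve_fit(logistic, x, y, p0=(L0, s0, o_init),
                                    bounds=bounds, sigma=sigma, maxfev=5000)
            except Exception:
                continue
            resid = logistic(x, *popt) - y
            cost = float(np.sum((resid / (sigma if sigma is not None else 1.0)) ** 2))
            if cost < best_cost - 1e-12:
                best, best_cost = popt, cost
    if best is None:
        raise FitError(
            f"{curve.metric_name}: sigmoid fit failed to converge from any "
            f"start; levels={x.tolist()}, means={curve.mean_value.tolist()}"
        )
    resid = float(np.linalg.norm(logistic(x, *best) - y))
    return SigmoidFit(L=float(best[0]), s=float(best[1]), o=float(best[2]),
                      residual_norm=resid, chance=chance, flipped=flipped)


def discrimination_threshold(fit: SigmoidFit, criterion: float) -> float | None:
    """Smallest ΔOri in [0°, 90°] where the fitted curve attains the criterion.

    Closed-form inversion of the logistic; the criterion is given on the
    metric's raw scale and transformed like the fit.  Returns ``None`` when
    the curve never reaches the criterion within [0°, 90°].
    """
    c = float(fit.transform(criterion))
    if c <= 0:
        return 0.0  # curve starts at/above the criterion
    if c >= fit.L:
        return None
    thr = fit.o - np.log(fit.L / c - 1.0) / fit.s
    if thr > 90.0:
        return None
    return float(max(thr, 0.0))


def threshold_for_metric(
    table: pd.DataFrame,
    metric_name: str,
    criterion: float,
    mask: np.ndarray | None = None,
    slices: list[TrialSlice] | None = None,
    geometry: Geometry | None = None,
    params: MetricParams | None = None,
) -> float | None:
    curve = build_curve(table, metric_name, mask=mask, slices=slices,
                        geometry=geometry, params=params)
    fit = fit_sigmoid(curve)
    return discrimination_threshold(fit, criterion)


def threshold_by_condition(
    table: pd.DataFrame,
    masks: dict[str, np.ndarray],
    criteria: dict[str, float] | None = None,
    slices: list[TrialSlice] | None = None,
    geometry: Geometry | None = None,
    params: MetricParams | None = None,
    metrics: tuple[str, ...] = THRESHOLD_METRICS,
) -> dict[str, ThresholdEstimate]:
    """Full curve → fit → threshold chain per condition mask.

    The per-condition estimate averages the defined per-metric thresholds;
    not-reached thresholds are excluded from the average and reported as
    ``None``.  Under-populated conditions are skipped with a reason.
    """
    criteria = dict(DEFAULT_CRITERIA, **(criteria or {}))
    out: dict[str, ThresholdEstimate] = {}
    for name, mask in masks.items():
        per_metric: dict[str, float | None] = {}
        n_trials = int((table["include_flag"].to_numpy() & np.asarray(mask, bool)).sum())
        try:
            for m in metrics:
                per_metric[m] = threshold_for_metric(
                    table, m, criteria[m], mask=mask, slices=slices,
                    geometry=geometry, params=params,
                )
        except (FitError, UndefinedMetricError) as exc:
            out[name] = ThresholdEstimate(
                condition=name, per_metric={"skipped": str(exc)},
                averaged=None, n_trials=n_trials,
            )
            continue
        defined = [v for v in per_metric.values() if v is not None]
        out[name] = ThresholdEstimate(
            condition=name,
            per_metric=per_metric,
            averaged=float(np.mean(defined)) if defined else None,
            n_trials=n_trials,
        )
    return out


__all__ = [
    "POLARITY",
    "DEFAULT_CRITERIA",
    "THRESHOLD_METRICS",
    "PsychometricCurve",
    "SigmoidFit",
    "CriterionSet",
    "ThresholdEstimate",
    "logistic",
    "build_curve",
    "bootstrap_criterion",
    "fit_sigmoid",
    "discrimination_threshold",
    "threshold_for_metric",
    "threshold_by_condition",
]
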