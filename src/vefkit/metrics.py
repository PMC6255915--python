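"""Primary single-trial performance metrics.

Seven metrics per left/right choice trial:

* **hit index** — +1 target touch, −1 distractor touch, 0 neither.
* **target distance (TD)** — |X_T − X_M| / ΔX_T, the lateral distance of
  the animal from the nearest target edge at the target's Y level,
  normalised by the spacing between adjacent target positions (0 = hit,
  ≈1 = one position off, ≈2 = opposite side).
* **path reliability (PR)** — the maximum over longitudinal grid positions
  of the pooled-SD Cohen's D between left-target and right-target lateral
  path positions; also computed per trial over a sliding 15-trial window
  ("local PR").
* **path surplus (PS)** — actual post-decision path length over the
  straight line from the decision point to the chosen target centre,
  minus 1.
* **reaction time (RT)** — the time at which the slope of the regression
  between a 20-sample lateral-path segment and the same segment shifted
  forward by 5 samples deviates most from 1.  The segment *ends* at the
  candidate time, so the statistic is attributed to the most recent sample
  (this recovers direction-change onsets within ±2 samples; a centred
  window would date them ~8 samples early).
* **lick position (LL)** — mean signed Y distance of licks from the target
  row within ±30 cm of it (negative = anticipatory), spanning the approach
  and the following trial's first stretch.
* **running speed** — mean virtual-plane speed from the target shift until
  the animal is within 10 cm of the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Geometry, MetricParams
from .errors import UndefinedMetricError
from .session_io import SessionData, TrialSlice, segment_trials

HIT_VALUES = {"target": 1, "distractor": -1, "neither": 0}

METRIC_COLUMNS = [
    "hit_index", "target_distance", "reaction_time", "path_surplus",
    "lick_position", "running_speed", "local_pr",
]


def _require_choice(trial: TrialSlice) -> None:
    if not trial.include_flag:
        raise UndefinedMetricError(
            f"trial {trial.trial_id}: metrics are undefined for "
            f"{'repeat' if trial.repeat_flag else trial.side} trials"
        )


# ---------------------------------------------------------------------------
# Hit index and target distance


def geometric_outcome(trial: TrialSlice, geom: Geometry) -> str:
    """Touch test from the trajectory endpoint at the target's Y level."""
    x_m = _x_at_target_level(trial, geom)
    lo, hi = geom.wall_span(trial.side)
    if lo <= x_m <= hi:
        return "target"
    if trial.side in ("left", "right"):
        dlo, dhi = geom.wall_span(Geometry.distractor_side(trial.side))
        if dlo <= x_m <= dhi:
            return "distractor"
    return "neither"


def hit_index(trial: TrialSlice, geom: Geometry) -> int:
    """+1 target touch, −1 distractor touch, 0 neither.

    The logged outcome event is authoritative; the geometric touch test is
    the fallback when the log carries no outcome.
    """
    _require_choice(trial)
    outcome = trial.outcome if trial.outcome in HIT_VALUES else geometric_outcome(trial, geom)
    return HIT_VALUES[outcome]


def _x_at_target_level(trial: TrialSlice, geom: Geometry) -> float:
    """Animal's lateral position at the target's Y level.

    Falls back to the final sample when the trial ends short of the target
    row.
    """
    reached = np.flatnonzero(trial.y >= geom.target_y - 1e-9)
    idx = reached[0] if len(reached) else len(trial.y) - 1
    return float(trial.x[idx])


def target_distance(trial: TrialSlice, geom: Geometry) -> float:
    """|X_T − X_M| / ΔX_T with X_T the target edge closest to the animal."""
    _require_choice(trial)
    if hit_index(trial, geom) == 1:
        return 0.0
    x_m = _x_at_target_level(trial, geom)
    lo, hi = geom.wall_span(trial.side)
    if lo <= x_m <= hi:
        return 0.0
    x_t = lo if x_m < lo else hi
    return abs(x_t - x_m) / geom.target_spacing


# ---------------------------------------------------------------------------
# Path reliability


@dataclass
class PRResult:
    """Cohen's D profile across the longitudinal grid and its maximum."""

    y_grid: np.ndarray
    d_profile: np.ndarray
    pr_score: float
    n_left: int
    n_right: int


def _binned_path(trial: TrialSlice, y_grid: np.ndarray, step: float) -> np.ndarray:
    """Mean lateral position per longitudinal bin ``[y_k, y_k + step)``."""
    out = np.full(len(y_grid), np.nan)
    y, x = trial.y, trial.x
    for k, y0 in enumerate(y_grid):
        m = (y >= y0) & (y < y0 + step)
        if m.any():
            out[k] = x[m].mean()
    # the target row itself (y == target_y) belongs to the last bin
    return out


def _pr_from_matrices(
    xl: np.ndarray, xr: np.ndarray, y_grid: np.ndarray
) -> PRResult | None:
    """Cohen's D profile from per-trial binned-path matrices (rows = trials)."""
    d = np.full(len(y_grid), np.nan)
    for k in range(len(y_grid)):
        a = xl[:, k][~np.isnan(xl[:, k])]
        b = xr[:, k][~np.isnan(xr[:, k])]
        n_l, n_r = len(a), len(b)
        if n_l < 2 or n_r < 2:
            continue
        pooled = np.sqrt(
            ((n_l - 1) * a.std(ddof=1) ** 2 + (n_r - 1) * b.std(ddof=1) ** 2)
            / (n_l + n_r - 2)
        )
        diff = abs(a.mean() - b.mean())
        if pooled == 0:
            d[k] = 0.0 if diff < 1e-12 else np.inf
        else:
            d[k] = diff / pooled
    if np.all(np.isnan(d)):
        return None
    score = float(np.nanmax(d))
    return PRResult(y_grid=y_grid, d_profile=d, pr_score=score,
                    n_left=len(xl), n_right=len(xr))


def path_reliability(
    trials: list[TrialSlice], geom: Geometry, params: MetricParams
) -> PRResult | None:
    """PR score of a trial set: max over Y of the left/right Cohen's D.

    Returns ``None`` (undefined) with fewer than two left or two right
    trials, where the pooled standard deviation does not exist.
    """
    lefts = [t for t in trials if t.include_flag and t.side == "left"]
    rights = [t for t in trials if t.include_flag and t.side == "right"]
    if len(lefts) < 2 or len(rights) < 2:
        return None
    step = params.pr_grid_step
    y_grid = np.arange(geom.trigger_y, geom.target_y + 1e-9, step)
    xl = np.vstack([_binned_path(t, y_grid, step) for t in lefts])
    xr = np.vstack([_binned_path(t, y_grid, step) for t in rights])
    return _pr_from_matrices(xl, xr, y_grid)


def local_path_reliability(
    ordered_trials: list[TrialSlice], geom: Geometry, params: MetricParams
) -> np.ndarray:
    """Per-trial PR over a sliding window of the trial ± half_window trials.

    Undefined (NaN) for the first and last ``half_window`` trials and for
    windows lacking two trials on either side.
    """
    h = params.local_pr_half_window
    n = len(ordered_trials)
    out = np.full(n, np.nan)
    if n < 2 * h + 1:
        return out
    step = params.pr_grid_step
    y_grid = np.arange(geom.trigger_y, geom.target_y + 1e-9, step)
    binned = np.vstack([_binned_path(t, y_grid, step) for t in ordered_trials])
    is_left = np.array([t.side == "left" for t in ordered_trials])
    is_right = np.array([t.side == "right" for t in ordered_trials])
    for i in range(h, n - h):
        w = slice(i - h, i + h + 1)
        xl = binned[w][is_left[w]]
        xr = binned[w][is_right[w]]
        if len(xl) < 2 or len(xr) < 2:
            continue
        res = _pr_from_matrices(xl, xr, y_grid)
        if res is not None:
            out[i] = res.pr_score
    return out


# ---------------------------------------------------------------------------
# Reaction time


def slope_deviation_profile(
    trial: TrialSlice, params: MetricParams
) -> tuple[np.ndarray, np.ndarray]:
    """|b_t − 1| for every sample t where the trailing window fits.

    b_t is the least-squares slope regressing the lateral-position segment
    shifted forward by ``rt_shift`` samples onto the segment ending at t.
    Zero-variance segments define b_t = 1 (no direction change).
    """
    w, d = params.rt_window, params.rt_shift
    x = trial.x
    n = len(x)
    if n < w + d:
        return np.array([]), np.array([])
    seg = np.lib.stride_tricks.sliding_window_view(x, w)  # seg[j] = x[j : j+w]
    a = seg[: n - w - d + 1]          # windows ending at t = j + w - 1
    b = seg[d : n - w + 1]            # same windows shifted by +d
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    var = (am * am).mean(axis=1)
    cov = (am * bm).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var > 1e-18, cov / np.where(var > 0, var, 1.0), 1.0)
    t_idx = np.arange(w - 1, n - d)   # sample index each statistic is attributed to
    return t_idx, np.abs(slope - 1.0)


def reaction_time(
    trial: TrialSlice, params: MetricParams
) -> tuple[float, str]:
    """(RT in seconds after the shift, reason) — RT is NaN when undefined.

    Candidates are restricted to post-shift times within ``rt_bounds`` and
    to the configured analysis span around the shift; the argmax of
    |b_t − 1| wins, earliest on ties; a maximum deviation below
    ``rt_slope_min_dev`` means the animal never substantially changed
    running direction and RT is undefined.
    """
    t_idx, dev = slope_deviation_profile(trial, params)
    if len(t_idx) == 0:
        return float("nan"), "trace_too_short"
    t_rel = trial.t_rel[t_idx]
    lo, hi = params.rt_bounds
    span_lo, span_hi = params.rt_analysis_span
    mask = (t_rel >= lo) & (t_rel <= hi) & (t_rel >= span_lo) & (t_rel <= span_hi)
    if not mask.any():
        return float("nan"), "no_candidates_in_bounds"
    dev = dev[mask]
    t_rel = t_rel[mask]
    if np.nanmax(dev) < params.rt_slope_min_dev:
        return float("nan"), "no_direction_change"
    best = int(np.argmax(dev))  # argmax returns the first (earliest) maximum
    return float(t_rel[best]), "ok"


# ---------------------------------------------------------------------------
# Path surplus


def path_surplus(
    trial: TrialSlice, rt: float, geom: Geometry
) -> float:
    """L_R / L_i − 1 from the decision point to the chosen target.

    The chosen target is the lateral target position the animal ended
    closest to (not necessarily the correct one); the ideal path runs from
    the position at the reaction time straight to that target's centre.
    Undefined (NaN) when RT is undefined.
    """
    _require_choice(trial)
    if not np.isfinite(rt):
        return float("nan")
    rel = trial.t_rel
    dec = int(np.searchsorted(rel, rt - 1e-9))
    dec = min(dec, len(rel) - 1)
    x_end = _x_at_target_level(trial, geom)
    centers = {s: geom.center_x(s) for s in ("left", "right")}
    chosen = min(centers, key=lambda s: abs(centers[s] - x_end))
    cx = centers[chosen]
    x0, y0 = trial.x[dec], trial.y[dec]
    l_ideal = float(np.hypot(cx - x0, geom.target_y - y0))
    if l_ideal < 1e-9:
        return float("nan")
    dx = np.diff(trial.x[dec:])
    dy = np.diff(trial.y[dec:])
    l_real = float(np.sum(np.hypot(dx, dy)))
    return l_real / l_ideal - 1.0


# ---------------------------------------------------------------------------
# Lick position and running speed


def lick_position(
    trial: TrialSlice,
    next_trial: TrialSlice | None,
    geom: Geometry,
    params: MetricParams,
) -> float:
    """Mean signed Y distance of licks from the target row (±lick_window).

    Negative values are anticipatory (before the target), positive values
    come from licks in the following trial's first stretch (after reward).
    Undefined (NaN) with no licks in the window.
    """
    w = params.lick_window
    d_vals = []
    m = (trial.lick > 0) & (trial.y >= geom.target_y - w)
    if m.any():
        d_vals.append(trial.y[m] - geom.target_y)
    if next_trial is not None:
        m2 = (next_trial.lick > 0) & (next_trial.y - geom.start_y <= w)
        if m2.any():
            d_vals.append(next_trial.y[m2] - geom.start_y)
    if not d_vals:
        return float("nan")
    return float(np.concatenate(d_vals).mean())


def running_speed(
    trial: TrialSlice, geom: Geometry, params: MetricParams
) -> tuple[float, bool]:
    """(mean speed cm/s from shift to within the stop radius, reached flag).

    Speed is the virtual-plane displacement per sample times the sampling
    rate.  If the animal never enters the radius the average runs to trial
    end and the flag is False.
    """
    _require_choice(trial)
    rel = trial.t_rel
    start = int(np.searchsorted(rel, -1e-9))
    cx = geom.center_x(trial.side)
    dist = np.hypot(trial.x - cx, trial.y - geom.target_y)
    inside = np.flatnonzero(dist[start:] <= params.speed_stop_radius)
    reached = len(inside) > 0
    stop = start + (inside[0] if reached else len(dist) - 1 - start)
    stop = max(stop, start + 1)
    dx = np.diff(trial.x[start : stop + 1])
    dy = np.diff(trial.y[start : stop + 1])
    speed = np.hypot(dx, dy) * trial.sample_rate
    return float(speed.mean()), reached


# ---------------------------------------------------------------------------
# Metric table


def compute_metric_table(
    session: SessionData,
    geom: Geometry | None = None,
    params: MetricParams | None = None,
) -> pd.DataFrame:
    """One row per event-log trial with all seven primary metrics.

    Metrics are NaN on excluded (centre / repeat) trials; per-metric
    undefined markers propagate without aborting the table.
    """
    geom = geom or session.geometry
    params = params or MetricParams()
    slices = segment_trials(session)
    inc = [s for s in slices if s.include_flag]
    local_pr = local_path_reliability(inc, geom, params)
    local_by_id = {s.trial_id: local_pr[i] for i, s in enumerate(inc)}

    next_included: dict[int, TrialSlice | None] = {}
    for i, s in enumerate(slices):
        next_included[s.trial_id] = slices[i + 1] if i + 1 < len(slices) else None

    rows = []
    for s in slices:
        row = dict(
            trial_id=s.trial_id, side=s.side, delta_ori=s.delta_ori,
            cue_flag=s.cue_flag, cue_type=s.cue_type, outcome=s.outcome,
            repeat_flag=s.repeat_flag, include_flag=s.include_flag,
            onset=s.onset, offset=s.offset, duration=s.duration,
            hit_index=np.nan, target_distance=np.nan, reaction_time=np.nan,
            rt_reason="excluded", path_surplus=np.nan, lick_position=np.nan,
            running_speed=np.nan, speed_reached_radius=False,
            local_pr=local_by_id.get(s.trial_id, np.nan),
        )
        if s.include_flag:
            row["hit_index"] = hit_index(s, geom)
            row["target_distance"] = target_distance(s, geom)
            rt, reason = reaction_time(s, params)
            row["reaction_time"] = rt
            row["rt_reason"] = reason
            row["path_surplus"] = path_surplus(s, rt, geom)
            row["lick_position"] = lick_position(s, next_included[s.trial_id], geom, params)
            speed, reached = running_speed(s, geom, params)
            row["running_speed"] = speed
            row["speed_reached_radius"] = reached
        rows.append(row)
    return pd.DataFrame(rows)


def write_metric_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in ("cue_flag", "repeat_flag", "include_flag", "speed_reached_radius"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def read_metric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("cue_flag", "repeat_flag", "include_flag", "speed_reached_radius"):
        df[col] = df[col].astype(int).astype(bool)
    for col in METRIC_COLUMNS + ["delta_ori", "onset", "offset", "duration"]:
        df[col] = pd.to_numeric(df[col])
    return df


__all__ = [
    "PRResult",
    "geometric_outcome",
    "hit_index",
    "target_distance",
    "path_reliability",
    "local_path_reliability",
    "slope_deviation_profile",
    "reaction_time",
    "path_surplus",
    "lick_position",
    "running_speed",
    "compute_metric_table",
    "write_metric_table",
    "read_metric_table",
    "METRIC_COLUMNS",
]
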