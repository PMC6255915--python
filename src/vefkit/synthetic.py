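"""Synthetic foraging-session generator.

Produces sessions (event log + 60 Hz continuous trace) with fully known
ground truth so that every downstream analysis stage can be tested by
parameter recovery: trajectory metrics, psychometric thresholds, alertness
segmentation, and the attention scores.

Generative model
----------------
* Side sequence: pseudo-randomised so that every complete block of
  ``block_size`` trials contains exactly ``trial_mix x block_size`` left /
  centre / right trials.
* Alertness: alternating high/low states with gamma dwell times
  (an alternating renewal process).
* Choice: on left/right trials the animal picks the target with probability
  given by a state-dependent logistic function of the orientation
  difference; error trials commit to the wrong side.  The logistic midpoint
  is placed analytically so that the *hit-index* psychometric curve crosses
  the conventional 0.2 criterion exactly at the configured per-state
  threshold (see :func:`hit_curve_params`).
* Trajectory: forward speed is white noise around a mean; lateral position
  jitters (mean-reverting) until the drawn true reaction time, then steers
  proportionally towards the chosen aim point; optional mid-course switches
  first steer towards the mirrored aim, inducing path surplus.
* Licks: inhomogeneous Poisson with a peri-target bump whose centre is
  shifted by the state-dependent anticipation offset, plus a post-reward
  plateau at the start of the following trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit
from scipy.stats import norm

from .config import (
    Geometry,
    Kinematics,
    SimConfig,
    StateProcess,
    StateTruth,
    config_to_dict,
    save_sim_config,
)
from .errors import ValidationError
from .session_io import (
    EVENT_COLUMNS,
    ContinuousTrace,
    EventLog,
    SessionData,
    TrialSlice,
    write_session,
)

HIT_CRITERION_ANCHOR = 0.2  # hit-index criterion the threshold truth is anchored to


# ---------------------------------------------------------------------------
# Psychometric truth plumbing


def commit_touch_probability(kin: Kinematics, geom: Geometry) -> float:
    """Probability that a committed run's endpoint stays on the chosen wall.

    Aims are uniform within the wall span minus the margin; the endpoint
    adds residual steering noise with the AR(1) stationary SD
    ``lateral_noise_sd / sqrt(2 * steering_gain)``.  Navigation is
    choice-conditional, so the same probability applies to target and
    distractor commits.
    """
    half = geom.target_width / 2.0
    m = min(kin.aim_margin, half)
    sigma = kin.lateral_noise_sd / np.sqrt(2.0 * kin.steering_gain)
    if sigma < 1e-9:
        return 1.0
    # average the in-span probability over the uniform aim offset
    a = np.linspace(-(half - m), half - m, 41)
    p = norm.cdf((half - a) / sigma) - norm.cdf((-half - a) / sigma)
    return float(p.mean())


def hit_curve_params(truth: StateTruth, kin: Kinematics, geom: Geometry) -> tuple[float, float]:
    """Logistic midpoint ``x0`` and commit-touch probability ``p_t``.

    With target-commit probability q(x) = 0.5 + (0.5 - lapse) * g(x),
    g(x) = expit(slope * (x - x0)), the population hit-index curve is
    H(x) = p_t * (2 q(x) - 1) — chance level exactly 0 because navigation
    is identical for either commit.  ``x0`` is chosen so that
    H(threshold) = 0.2, anchoring the configured threshold to the
    hit-index criterion crossing.
    """
    p_t = commit_touch_probability(kin, geom)
    q_star = 0.5 + HIT_CRITERION_ANCHOR / (2.0 * p_t)
    g_star = (q_star - 0.5) / (0.5 - truth.lapse) if truth.lapse < 0.5 else np.nan
    if not 0 < g_star < 1:
        # lapse-dominated state: its hit curve never reaches the criterion,
        # so the threshold parameter anchors the logistic midpoint instead
        return truth.threshold, p_t
    x0 = truth.threshold - float(logit(g_star)) / truth.slope
    return x0, p_t


def discriminability(
    delta_ori: float, truth: StateTruth, kin: Kinematics, geom: Geometry,
    accuracy_boost: float = 0.0,
) -> float:
    """g(ΔOri) in [0, 1]: 0 at chance, 1 at full discrimination."""
    x0, _ = hit_curve_params(truth, kin, geom)
    return float(expit(truth.slope * (delta_ori - (x0 - accuracy_boost))))


def correct_probability(
    delta_ori: float,
    truth: StateTruth,
    kin: Kinematics,
    geom: Geometry,
    accuracy_boost: float = 0.0,
) -> float:
    """Probability of committing to the target side."""
    g = discriminability(delta_ori, truth, kin, geom, accuracy_boost)
    return 0.5 + (0.5 - truth.lapse) * g


def analytic_chance_td(geom: Geometry) -> float:
    """Population target distance at zero discriminability.

    Wrong-side commits touch the distractor wall (mean |X| = the centre
    magnitude), correct commits give TD 0, and commits split 50/50 at
    chance: chance TD = 0.5 * (centre spacing*2 - width/2 ... ) / spacing.
    """
    near_edge = abs(geom.center_x("left")) - geom.target_width / 2.0
    mean_wrong = (abs(geom.center_x("right")) + near_edge) / geom.target_spacing
    return 0.5 * mean_wrong


# ---------------------------------------------------------------------------
# Alertness state sequence


def generate_state_sequence(
    state_process: StateProcess,
    duration: float,
    seed_or_rng: int | np.random.Generator,
) -> list[tuple[str, float, float]]:
    """Tile ``[0, duration]`` with alternating high/low dwell segments."""
    if duration <= 0:
        raise ValidationError(f"session duration must be positive, got {duration}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    mh, ml = state_process.mean_dwell_high, state_process.mean_dwell_low
    if mh == 0:
        return [("low", 0.0, float(duration))]
    if ml == 0:
        return [("high", 0.0, float(duration))]
    state = "high" if rng.random() < mh / (mh + ml) else "low"
    k = state_process.shape
    segments = []
    t = 0.0
    while t < duration:
        mean = mh if state == "high" else ml
        dwell = float(rng.gamma(k, mean / k))
        dwell = max(dwell, 1e-6)
        end = min(t + dwell, duration)
        segments.append((state, t, end))
        t = end
        state = "low" if state == "high" else "high"
    return segments


def state_at(segments: list[tuple[str, float, float]], t: float) -> str:
    for state, start, end in segments:
        if start <= t < end:
            return state
    return segments[-1][0]


# ---------------------------------------------------------------------------
# Single-trial trajectory synthesis


@dataclass(frozen=True)
class TrialSpec:
    side: str
    delta_ori: float  # NaN on centre trials
    cue_flag: bool = False
    cue_type: str = "none"
    repeat_flag: bool = False


@dataclass
class SimTrial:
    spec: TrialSpec
    state: str
    x: np.ndarray
    y: np.ndarray
    lick: np.ndarray
    shift_idx: int
    end_idx: int
    n_gap: int
    outcome: str
    true_rt: float
    aim_x: float
    correct: bool
    reward_ul: float


def _ar1(a: float, u: np.ndarray, x0: float) -> np.ndarray:
    """x_t = a * x_{t-1} + u_t with x_{-1} = x0 (vectorised AR(1))."""
    out, _ = lfilter([1.0], [1.0, -a], u, zi=np.asarray([a * x0]))
    return out


def generate_trial(
    spec: TrialSpec,
    state: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    prev_rewarded: bool = False,
) -> SimTrial:
    """Simulate one trial (inter-trial gap + run) at the configured rate."""
    geom = cfg.geometry
    kin = cfg.kinematics_low if (state == "low" and cfg.kinematics_low is not None) else cfg.kinematics
    fs = cfg.sample_rate
    dt = 1.0 / fs
    is_choice = spec.side in ("left", "right")
    if is_choice and spec.delta_ori not in cfg.delta_ori_levels:
        raise ValidationError(
            f"delta_ori {spec.delta_ori} not among configured levels {cfg.delta_ori_levels}"
        )

    # --- forward motion -----------------------------------------------------
    v_mean = kin.forward_speed_mean
    if spec.cue_flag and spec.cue_type == "speed":
        v_mean += cfg.cue.speed_boost
    run_len = geom.target_y - geom.start_y
    n_max = int(np.ceil(run_len / max(v_mean * 0.4, 1.0) * fs)) + int(2 * fs)
    v = v_mean + kin.forward_speed_sd * rng.standard_normal(n_max)
    np.clip(v, 0.3 * v_mean, None, out=v)
    y = geom.start_y + np.cumsum(v * dt)
    shift_idx = int(np.searchsorted(y, geom.trigger_y))
    end_idx = int(np.searchsorted(y, geom.target_y))
    end_idx = min(end_idx, n_max - 1)
    np.clip(y, geom.start_y, geom.target_y, out=y)

    # --- choice and decision time -------------------------------------------
    truth = cfg.truth(state)
    rt_stats = cfg.rt_stats(state)
    half = geom.target_width / 2.0
    margin = min(kin.aim_margin, half)
    if is_choice:
        boost = cfg.cue.accuracy_boost if (spec.cue_flag and spec.cue_type == "accuracy") else 0.0
        g = discriminability(spec.delta_ori, truth, kin, geom, accuracy_boost=boost)
        q = 0.5 + (0.5 - truth.lapse) * g
        correct = bool(rng.random() < q)
        rt_mean = rt_stats.mean + cfg.rt_difficulty_shift * (1.0 - g)
        if spec.cue_flag and spec.cue_type == "speed":
            rt_mean += cfg.cue.rt_shift
        true_rt = float(np.clip(rng.normal(rt_mean, rt_stats.sd), 0.15, 1.05))
        chosen_side = spec.side if correct else Geometry.distractor_side(spec.side)
        if kin.aim_spread_sd is not None:
            aim = geom.center_x(chosen_side) + rng.normal(0.0, kin.aim_spread_sd)
        else:
            aim = geom.center_x(chosen_side) + rng.uniform(-(half - margin), half - margin)
        p_switch = min(kin.switch_prob + kin.switch_prob_hard * (1.0 - g), 1.0)
        switched = bool(rng.random() < p_switch)
    else:
        correct = True
        true_rt = float("nan")
        aim = float(rng.uniform(-(half - margin), half - margin))
        switched = False
    decision_idx = (
        shift_idx + int(round(true_rt * fs)) if is_choice else shift_idx
    )
    decision_idx = min(decision_idx, end_idx)

    # --- lateral motion ------------------------------------------------------
    noise = kin.lateral_noise_sd * np.sqrt(dt) * rng.standard_normal(n_max)
    x = np.empty(n_max)
    revert = 1.0  # 1/s mean reversion of the pre-decision jitter
    a_pre = 1.0 - revert * dt
    x[:decision_idx] = _ar1(a_pre, noise[:decision_idx], 0.0)
    x_dec = x[decision_idx - 1] if decision_idx > 0 else 0.0
    n_post = n_max - decision_idx
    if n_post > 0:
        aim_arr = np.full(n_post, aim)
        if switched:
            n_sw = int(round(kin.switch_duration * fs))
            aim_arr[:n_sw] = -aim
        a_post = 1.0 - kin.steering_gain * dt
        u = kin.steering_gain * dt * aim_arr + noise[decision_idx:]
        x[decision_idx:] = _ar1(a_post, u, x_dec)
    np.clip(x, -geom.lateral_bound, geom.lateral_bound, out=x)

    # --- outcome -------------------------------------------------------------
    x_m = x[end_idx]
    target_side = spec.side
    lo, hi = geom.wall_span(target_side)
    if lo <= x_m <= hi:
        outcome = "target"
    elif is_choice:
        dlo, dhi = geom.wall_span(Geometry.distractor_side(target_side))
        outcome = "distractor" if dlo <= x_m <= dhi else "neither"
    else:
        outcome = "neither"
    reward = cfg.reward_ul if outcome == "target" else 0.0
    if outcome == "target" and spec.cue_flag:
        reward *= 2.0

    # --- assemble gap + run, licks ------------------------------------------
    n_gap = int(round(cfg.intertrial_gap * fs))
    n_run = end_idx + 1
    xx = np.concatenate([np.zeros(n_gap), x[:n_run]])
    yy = np.concatenate([np.full(n_gap, geom.start_y), y[:n_run]])
    lick_model = cfg.lick_model
    centre = geom.target_y + lick_model.offset(state)
    rate = lick_model.baseline_rate + lick_model.peri_rate * np.exp(
        -((yy - centre) ** 2) / (2.0 * lick_model.peri_width**2)
    )
    if prev_rewarded:
        n_post_rw = min(n_gap, int(round(lick_model.post_reward_duration * fs)))
        rate[:n_post_rw] = np.maximum(rate[:n_post_rw], lick_model.post_reward_rate)
    lick = (rng.random(n_gap + n_run) < rate * dt).astype(int)

    return SimTrial(
        spec=spec,
        state=state,
        x=np.round(xx, 6),
        y=np.round(yy, 6),
        lick=lick,
        shift_idx=n_gap + shift_idx,
        end_idx=n_gap + end_idx,
        n_gap=n_gap,
        outcome=outcome,
        true_rt=true_rt,
        aim_x=float(aim),
        correct=correct,
        reward_ul=reward,
    )


# ---------------------------------------------------------------------------
# Session assembly


@dataclass
class GroundTruth:
    """Per-trial truth and state segmentation of a simulated session."""

    trials: pd.DataFrame
    segments: pd.DataFrame
    config: SimConfig = None


def _side_sequence(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Block-pseudo-randomised side labels (exact counts per complete block)."""
    counts = [int(round(p * cfg.block_size)) for p in cfg.trial_mix]
    block = (["left"] * counts[0] + ["centre"] * counts[1] + ["right"] * counts[2])
    sides: list[str] = []
    while len(sides) < cfg.n_trials:
        perm = list(rng.permutation(block))
        sides.extend(perm)
    return sides[: cfg.n_trials]


def generate_session(cfg: SimConfig) -> tuple[SessionData, GroundTruth]:
    """Simulate a full session; deterministic given ``cfg`` (incl. its seed)."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    geom = cfg.geometry

    sides = _side_sequence(cfg, rng)
    choice_idx = [i for i, s in enumerate(sides) if s != "centre"]
    deltas = {
        i: float(rng.choice(cfg.delta_ori_levels)) for i in choice_idx
    }
    n_cued = int(round(cfg.cue.fraction * len(choice_idx)))
    cued = set(
        rng.choice(np.asarray(choice_idx), size=n_cued, replace=False).tolist()
        if n_cued > 0
        else []
    )

    # generous duration bound for the pre-generated state sequence
    est_trial = cfg.intertrial_gap + (geom.target_y - geom.start_y) / (
        0.5 * cfg.kinematics.forward_speed_mean
    )
    duration_bound = 2.0 * cfg.n_trials * est_trial + 60.0
    segments = generate_state_sequence(cfg.state_process, duration_bound, rng)

    ev_rows = []
    gt_rows = []
    xs, ys, licks = [], [], []
    g = 0  # global sample counter
    prev_rewarded = False
    trial_id = 0
    queue: list[TrialSpec] = [
        TrialSpec(
            side=s,
            delta_ori=deltas.get(i, float("nan")),
            cue_flag=i in cued,
            cue_type=cfg.cue.type if i in cued else "none",
        )
        for i, s in enumerate(sides)
    ]
    queue.reverse()  # pop from the end
    while queue:
        spec = queue.pop()
        t_onset = g / fs
        state = state_at(segments, t_onset)
        trial = generate_trial(spec, state, cfg, rng, prev_rewarded=prev_rewarded)
        n = len(trial.x)
        ev_rows.append(
            dict(
                trial_id=trial_id,
                onset=round(g / fs, 6),
                offset=round((g + n) / fs, 6),
                shift_time=round((g + trial.shift_idx) / fs, 6),
                side=spec.side,
                delta_ori=spec.delta_ori,
                cue_flag=spec.cue_flag,
                cue_type=spec.cue_type,
                outcome=trial.outcome,
                reward_ul=trial.reward_ul,
                repeat_flag=spec.repeat_flag,
            )
        )
        gt_rows.append(
            dict(
                trial_id=trial_id,
                side=spec.side,
                delta_ori=spec.delta_ori,
                cue_flag=spec.cue_flag,
                state=trial.state,
                outcome=trial.outcome,
                correct=trial.correct,
                true_rt=trial.true_rt,
                aim_x=trial.aim_x,
                repeat_flag=spec.repeat_flag,
            )
        )
        xs.append(trial.x)
        ys.append(trial.y)
        licks.append(trial.lick)
        g += n
        trial_id += 1
        prev_rewarded = trial.outcome == "target"
        if (
            cfg.repeat_after_error
            and spec.side != "centre"
            and not spec.repeat_flag
            and trial.outcome != "target"
        ):
            queue.append(
                TrialSpec(
                    side=spec.side,
                    delta_ori=spec.delta_ori,
                    cue_flag=spec.cue_flag,
                    cue_type=spec.cue_type,
                    repeat_flag=True,
                )
            )

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    lick = np.concatenate(licks)
    n_total = len(x)
    time = np.round(np.arange(n_total) / fs, 6)
    tf = geom.translation_factor
    fwd = np.round(np.concatenate([[0.0], np.diff(y)]) * tf, 6)
    lat = np.round(np.concatenate([[0.0], np.diff(x)]) * tf, 6)

    trace = ContinuousTrace(
        pd.DataFrame(
            {"time": time, "x": x, "y": y, "fwd": fwd, "lat": lat, "lick": lick}
        ),
        sample_rate=fs,
    )
    events = EventLog(pd.DataFrame(ev_rows, columns=EVENT_COLUMNS))
    total_duration = n_total / fs
    seg_df = pd.DataFrame(
        [
            {"state": s, "start": max(a, 0.0), "end": min(b, total_duration)}
            for s, a, b in segments
            if a < total_duration
        ]
    )
    metadata = {
        "animal_id": "sim",
        "session_id": f"sim-{cfg.seed}",
        "training_stage": 6,
        "sample_rate": fs,
        "geometry": config_to_dict(geom),
        "seed": cfg.seed,
    }
    session = SessionData(events, trace, metadata)
    truth = GroundTruth(
        trials=pd.DataFrame(gt_rows), segments=seg_df, config=cfg
    )
    return session, truth


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials = truth.trials.copy()
    for col in ("cue_flag", "repeat_flag", "correct"):
        trials[col] = trials[col].astype(int)
    trials.to_csv(directory / "truth.tsv", sep="\t", index=False,
                  float_format="%.6f", na_rep="NA")
    truth.segments.to_csv(directory / "segments.tsv", sep="\t", index=False,
                          float_format="%.6f")
    if truth.config is not None:
        save_sim_config(truth.config, directory / "sim_config.yaml")


def simulate_to_dir(cfg: SimConfig, directory: str | Path) -> tuple[SessionData, GroundTruth]:
    session, truth = generate_session(cfg)
    write_session(session, directory)
    write_ground_truth(truth, Path(directory))
    return session, truth


# ---------------------------------------------------------------------------
# Constructed fixtures for estimator checks


def direction_change_slice(
    rt_true: float,
    law: str = "linear",
    drift_rate: float = 8.0,
    steering_gain: float = 3.0,
    noise_sd: float = 0.0,
    pre_shift: float = 1.0,
    post_shift: float = 3.0,
    sample_rate: float = 60.0,
    seed: int = 0,
    geometry: Geometry | None = None,
) -> TrialSlice:
    """A single-trial slice with a lateral direction change at a known time.

    The lateral position is flat (up to optional random-walk jitter) until
    ``rt_true`` seconds after the target shift, then either drifts linearly
    (``law='linear'``) or steers exponentially towards a fixed aim point
    (``law='exponential'``).
    """
    geom = geometry or Geometry()
    fs = sample_rate
    rng = np.random.default_rng(seed)
    n = int(round((pre_shift + post_shift) * fs))
    t = np.arange(n) / fs
    shift_time = pre_shift
    onset = shift_time + rt_true
    rel = t - onset
    if law == "linear":
        x = np.maximum(0.0, rel) * drift_rate
    elif law == "exponential":
        x = np.where(rel >= 0, 12.0 * (1.0 - np.exp(-steering_gain * np.maximum(rel, 0.0))), 0.0)
    else:
        raise ValidationError(f"unknown steering law {law!r}")
    if noise_sd > 0:
        x = x + np.cumsum(rng.normal(0.0, noise_sd / np.sqrt(fs), n))
    y = np.linspace(geom.start_y, geom.target_y, n)
    return TrialSlice(
        trial_id=0,
        side="right",
        delta_ori=90.0,
        cue_flag=False,
        cue_type="none",
        outcome="target",
        repeat_flag=False,
        onset=0.0,
        offset=n / fs,
        shift_time=shift_time,
        time=t,
        x=x,
        y=y,
        lick=np.zeros(n, dtype=int),
        sample_rate=fs,
        include_flag=True,
    )


# ---------------------------------------------------------------------------
# Metric-level cue-effect generator (for the cued-attention score)


def simulate_cue_effect_table(
    n_trials: int = 500,
    cue_fraction: float = 0.2,
    cl_reduction: float = 0.3,
    seed: int = 0,
    rt_dist: tuple[float, float] = (0.55, 0.12),
    td_dist: tuple[float, float] = (0.60, 0.30),
    ps_dist: tuple[float, float] = (0.40, 0.25),
) -> pd.DataFrame:
    """Per-trial metric table whose cued trials carry a configured CL deficit.

    Draws reaction time, target distance and path surplus from normal
    distributions and shifts the cued trials' values down by amounts solved
    analytically so that the population cognitive-load index satisfies
    ``(CL_noncued - CL_cued) / CL_all = cl_reduction`` under the 5th/95th
    percentile normalisation actually used by the scoring code.
    """
    if not 0 < cue_fraction < 1:
        raise ValidationError("cue_fraction must lie strictly between 0 and 1")
    dists = {"reaction_time": rt_dist, "target_distance": td_dist, "path_surplus": ps_dist}
    f = cue_fraction

    def mixture_quantile(mu: float, sd: float, shift: float, p: float) -> float:
        from scipy.optimize import brentq

        def cdf(v):
            return (1 - f) * norm.cdf(v, mu, sd) + f * norm.cdf(v, mu - shift, sd) - p

        lo = mu - shift - 8 * sd
        hi = mu + 8 * sd
        return float(brentq(cdf, lo, hi))

    # population normalised non-cued mean for one metric, given the shift
    def norm_mean_and_range(mu, sd, shift):
        q5 = mixture_quantile(mu, sd, shift, 0.05)
        q95 = mixture_quantile(mu, sd, shift, 0.95)
        rng_m = q95 - q5
        return (mu - q5) / rng_m, rng_m

    weights = {"reaction_time": 0.5, "target_distance": 0.25, "path_surplus": 0.25}

    def raw_shift_for(mu: float, sd: float, delta: float) -> float:
        # solve Delta = delta * range(Delta) (the range itself depends on
        # the cued shift through the pooled-mixture quantiles)
        shift = delta * (norm.ppf(0.95) - norm.ppf(0.05)) * sd
        for _ in range(30):
            _, rng_m = norm_mean_and_range(mu, sd, shift)
            new = delta * rng_m
            if abs(new - shift) < 1e-12:
                return new
            shift = new
        return shift

    # outer fixed point on the common normalised shift delta:
    # delta = cl_reduction * CL_all(delta)
    delta = cl_reduction * 0.5
    shifts = {}
    for _ in range(60):
        cl_nc = 0.0
        for m, (mu, sd) in dists.items():
            shifts[m] = raw_shift_for(mu, sd, delta)
            nu, _ = norm_mean_and_range(mu, sd, shifts[m])
            cl_nc += weights[m] * nu
        cl_all = cl_nc - f * delta
        new_delta = cl_reduction * cl_all
        if abs(new_delta - delta) < 1e-12:
            delta = new_delta
            break
        delta = new_delta
    for m, (mu, sd) in dists.items():
        shifts[m] = raw_shift_for(mu, sd, delta)

    rng = np.random.default_rng(seed)
    cue_flags = np.zeros(n_trials, dtype=bool)
    n_cued = int(round(f * n_trials))
    cue_flags[rng.choice(n_trials, size=n_cued, replace=False)] = True
    data = {"cue_flag": cue_flags}
    for m, (mu, sd) in dists.items():
        vals = rng.normal(mu, sd, n_trials)
        vals[cue_flags] -= shifts[m]
        data[m] = vals
    table = pd.DataFrame(data)
    table["trial_id"] = np.arange(n_trials)
    table["side"] = np.where(np.arange(n_trials) % 2 == 0, "left", "right")
    table["include_flag"] = True
    table["hit_index"] = 1.0
    table["cue_type"] = np.where(cue_flags, "speed", "none")
    return table


__all__ = [
    "TrialSpec",
    "SimTrial",
    "GroundTruth",
    "generate_state_sequence",
    "state_at",
    "generate_trial",
    "generate_session",
    "write_ground_truth",
    "simulate_to_dir",
    "direction_change_slice",
    "simulate_cue_effect_table",
    "hit_curve_params",
    "correct_probability",
    "discriminability",
    "commit_touch_probability",
    "analytic_chance_td",
    "HIT_CRITERION_ANCHOR",
]
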