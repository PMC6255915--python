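"""Configuration objects: arena geometry, metric parameters, simulation config.

All objects are plain dataclasses with YAML round-trip support so that every
pipeline run can be reproduced from a single config file plus a seed.

Units: centimetres for positions, seconds for times, Hz for rates, degrees
for grating-orientation differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ValidationError

SIDES = ("left", "centre", "right")
STATES = ("high", "low")
CUE_TYPES = ("speed", "accuracy", "none")


@dataclass(frozen=True)
class Geometry:
    """Spatial layout of the virtual corridor.

    The animal starts at ``(0, start_y)``, triggers the target shift when it
    crosses ``trigger_y``, and the trial ends when it reaches the target wall
    row at ``target_y``.  Targets are wall segments of width ``target_width``
    centred on ``target_centers_x``; ``target_spacing`` is the distance
    between adjacent target centres and is the normalisation constant of the
    target-distance metric.
    """

    start_y: float = 0.0
    trigger_y: float = 20.0
    target_y: float = 48.0
    target_centers_x: tuple[float, float, float] = (-12.0, 0.0, 12.0)
    target_width: float = 9.0
    lateral_bound: float = 24.0
    target_spacing: float = 12.0
    translation_factor: float = 3.0

    def __post_init__(self) -> None:
        if not (self.start_y < self.trigger_y < self.target_y):
            raise ValidationError(
                "geometry requires start_y < trigger_y < target_y, got "
                f"{self.start_y}, {self.trigger_y}, {self.target_y}"
            )
        if self.target_width <= 0:
            raise ValidationError("target_width must be positive")
        left, centre, right = self.target_centers_x
        if not (left < centre < right):
            raise ValidationError("target centres must be ordered left < centre < right")

    def center_x(self, side: str) -> float:
        return self.target_centers_x[SIDES.index(side)]

    def wall_span(self, side: str) -> tuple[float, float]:
        c = self.center_x(side)
        half = self.target_width / 2.0
        return (c - half, c + half)

    @staticmethod
    def distractor_side(side: str) -> str:
        if side == "left":
            return "right"
        if side == "right":
            return "left"
        raise ValidationError(f"centre trials have no distractor (side={side!r})")


@dataclass(frozen=True)
class MetricParams:
    """Tunable parameters of the primary single-trial metrics.

    ``rt_window`` is the total number of samples in each regression segment
    and ``rt_shift`` the forward shift (in samples) between the two segments
    compared by the reaction-time slope regression.
    """

    rt_window: int = 20
    rt_shift: int = 5
    rt_bounds: tuple[float, float] = (0.1, 1.25)
    rt_slope_min_dev: float = 0.1
    rt_analysis_span: tuple[float, float] = (-0.5, 3.0)
    pr_grid_step: float = 2.0
    local_pr_half_window: int = 7
    lick_window: float = 30.0
    speed_stop_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.rt_window < 4 or self.rt_shift < 1:
            raise ValidationError("rt_window >= 4 and rt_shift >= 1 required")
        lo, hi = self.rt_bounds
        if not (0 <= lo < hi):
            raise ValidationError("rt_bounds must satisfy 0 <= lo < hi")
        if min(self.pr_grid_step, self.lick_window, self.speed_stop_radius) <= 0:
            raise ValidationError("pr_grid_step, lick_window, speed_stop_radius must be positive")
        if self.local_pr_half_window < 1:
            raise ValidationError("local_pr_half_window must be >= 1")


@dataclass(frozen=True)
class StateTruth:
    """Per-state psychometric ground truth.

    ``threshold`` is the orientation difference (deg) at which the hit-index
    psychometric curve crosses the conventional 0.2 criterion; ``slope`` the
    logistic steepness per degree; ``lapse`` the asymptotic error rate.
    """

    threshold: float = 10.0
    slope: float = 0.8
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.lapse <= 0.5:
            raise ValidationError("lapse must lie in [0, 0.5]")
        if self.slope <= 0 or self.threshold < 0:
            raise ValidationError("slope must be > 0 and threshold >= 0")


@dataclass(frozen=True)
class StateProcess:
    """Alternating-renewal alertness dynamics (gamma dwell times).

    ``shape`` is the gamma shape parameter for both states; 1.0 gives
    exponential dwells, larger values give more regular alternation.
    """

    mean_dwell_high: float = 300.0
    mean_dwell_low: float = 300.0
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_dwell_high < 0 or self.mean_dwell_low < 0:
            raise ValidationError("dwell means must be >= 0")
        if self.mean_dwell_high == 0 and self.mean_dwell_low == 0:
            raise ValidationError("at least one dwell mean must be positive")
        if self.shape <= 0:
            raise ValidationError("gamma shape must be positive")


@dataclass(frozen=True)
class RTStats:
    mean: float = 0.45
    sd: float = 0.12

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValidationError("RT mean must be > 0 and sd >= 0")


@dataclass(frozen=True)
class CueConfig:
    """Cued-trial incentive model.

    ``fraction`` of choice trials carries an auditory cue.  A ``speed`` cue
    shifts the drawn true reaction time by ``rt_shift`` (negative = faster)
    and adds ``speed_boost`` cm/s of running speed; an ``accuracy`` cue
    shifts the psychometric midpoint by ``accuracy_boost`` degrees towards
    better discrimination.
    """

    fraction: float = 0.2
    type: str = "speed"
    accuracy_boost: float = 4.0
    rt_shift: float = -0.1
    speed_boost: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValidationError("cue fraction must lie in [0, 1]")
        if self.type not in CUE_TYPES:
            raise ValidationError(f"cue type must be one of {CUE_TYPES}")


@dataclass(frozen=True)
class Kinematics:
    """Trajectory law parameters.

    Forward speed is white-noise around a mean; lateral position performs a
    small mean-reverting jitter before the decision point and proportional
    steering towards the chosen aim point afterwards.  The animal commits
    to a side (the target side with the psychometric probability) and homes
    onto that side's wall: the aim point is uniform within the wall span
    minus ``aim_margin`` at each edge, identically for correct and error
    commits.  A mid-course switch (steering first to the mirrored aim)
    occurs with probability ``switch_prob + switch_prob_hard * (1 - g)``
    where g is the trial's discriminability, so changes of mind concentrate
    on difficult trials.
    """

    forward_speed_mean: float = 15.0
    forward_speed_sd: float = 1.5
    steering_gain: float = 3.0
    lateral_noise_sd: float = 1.0
    switch_prob: float = 0.03
    switch_prob_hard: float = 0.30
    switch_duration: float = 0.35
    aim_margin: float = 0.75
    #: when set, aim points are Gaussian around the chosen wall's centre
    #: with this SD (cm) instead of uniform within the span — emulates
    #: animals with loose lateral targeting (more run-past-the-wall trials,
    #: moderate path-reliability ceiling)
    aim_spread_sd: float | None = None

    def __post_init__(self) -> None:
        if self.forward_speed_mean <= 0:
            raise ValidationError("forward_speed_mean must be positive")
        if self.steering_gain <= 0:
            raise ValidationError("steering_gain must be positive")
        for p in (self.switch_prob, self.switch_prob_hard):
            if not 0 <= p <= 1:
                raise ValidationError("switch probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class LickModel:
    """Inhomogeneous-Poisson lick emission.

    Rate = baseline + a Gaussian bump (width ``peri_width`` cm) centred at
    ``target_y + anticipation_offset[state]``; a post-reward plateau of
    ``post_reward_rate`` Hz runs for ``post_reward_duration`` s into the
    next trial after rewarded trials.
    """

    baseline_rate: float = 0.3
    peri_rate: float = 6.0
    peri_width: float = 8.0
    anticipation_offset_high: float = -8.0
    anticipation_offset_low: float = -1.0
    post_reward_rate: float = 6.0
    post_reward_duration: float = 0.8

    def offset(self, state: str) -> float:
        return self.anticipation_offset_high if state == "high" else self.anticipation_offset_low

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.peri_rate < 0 or self.post_reward_rate < 0:
            raise ValidationError("lick rates must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated foraging session."""

    n_trials: int = 300
    trial_mix: tuple[float, float, float] = (0.4, 0.2, 0.4)
    block_size: int = 10
    delta_ori_levels: tuple[float, ...] = (90.0, 70.0, 50.0, 30.0, 20.0, 15.0, 10.0, 5.0)
    truth_high: StateTruth = field(default_factory=StateTruth)
    truth_low: StateTruth = field(default_factory=lambda: StateTruth(threshold=16.0, lapse=0.05))
    state_process: StateProcess = field(default_factory=StateProcess)
    rt_high: RTStats = field(default_factory=lambda: RTStats(0.40, 0.10))
    rt_low: RTStats = field(default_factory=lambda: RTStats(0.55, 0.15))
    rt_difficulty_shift: float = 0.10  # extra mean RT (s) at zero discriminability
    cue: CueConfig = field(default_factory=CueConfig)
    kinematics: Kinematics = field(default_factory=Kinematics)
    #: optional kinematics override for the low-alert state (e.g. looser
    #: lateral targeting); None means both states share ``kinematics``
    kinematics_low: Kinematics | None = None
    lick_model: LickModel = field(default_factory=LickModel)
    geometry: Geometry = field(default_factory=Geometry)
    sample_rate: float = 60.0
    intertrial_gap: float = 0.5
    reward_ul: float = 10.0
    repeat_after_error: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        mix = self.trial_mix
        if len(mix) != 3 or any(p < 0 or p > 1 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValidationError("trial_mix must be three probabilities summing to 1")
        if self.block_size < 1:
            raise ValidationError("block_size must be >= 1")
        counts = [p * self.block_size for p in mix]
        if any(abs(c - round(c)) > 1e-9 for c in counts):
            raise ValidationError(
                "trial_mix x block_size must give whole per-block side counts "
                f"(got {counts})"
            )
        if len(self.delta_ori_levels) == 0:
            raise ValidationError("at least one delta_ori level is required")

    def truth(self, state: str) -> StateTruth:
        return self.truth_high if state == "high" else self.truth_low

    def rt_stats(self, state: str) -> RTStats:
        return self.rt_high if state == "high" else self.rt_low


# ---------------------------------------------------------------------------
# YAML round trip

_NESTED = {
    "truth_high": StateTruth,
    "truth_low": StateTruth,
    "state_process": StateProcess,
    "rt_high": RTStats,
    "rt_low": RTStats,
    "cue": CueConfig,
    "kinematics": Kinematics,
    "lick_model": LickModel,
    "geometry": Geometry,
}


def _tupleize(obj):
    if isinstance(obj, tuple):
        return [_tupleize(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    d = asdict(cfg)
    return {k: _tupleize(v) if not isinstance(v, dict) else v for k, v in d.items()}


def sim_config_from_dict(d: dict) -> SimConfig:
    kwargs = {}
    for key, value in d.items():
        if key == "kinematics_low":
            kwargs[key] = None if value is None else Kinematics(**value)
        elif key in _NESTED:
            kwargs[key] = _NESTED[key](**value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    try:
        return sim_config_from_dict(data)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def save_sim_config(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def geometry_from_dict(d: dict) -> Geometry:
    return Geometry(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


def metric_params_from_dict(d: dict) -> MetricParams:
    return MetricParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


__all__ = [
    "Geometry",
    "MetricParams",
    "StateTruth",
    "StateProcess",
    "RTStats",
    "CueConfig",
    "Kinematics",
    "LickModel",
    "SimConfig",
    "SIDES",
    "STATES",
    "config_to_dict",
    "sim_config_from_dict",
    "load_sim_config",
    "save_sim_config",
    "geometry_from_dict",
    "metric_params_from_dict",
    "replace",
]
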