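"""Alertness-state segmentation from local path-reliability scores.

An animal's local PR scores form a bimodal distribution when its behaviour
alternates between high- and low-alert episodes.  Bimodality is assessed
with the bimodality coefficient

    BC = (skew^2 + 1) / (kurt - 3 + 3 (n-1)^2 / ((n-2)(n-3))),

using the sample skewness and the raw (non-excess) fourth standardised
moment; BC > 0.55 flags a bimodal distribution.  The cut between modes is
the point maximising the variance-ratio statistic

    F = Var_all / mean(Var_below, Var_above),

scanned exhaustively over the midpoints between consecutive sorted unique
values.  Trials whose local PR exceeds the cut are high-alert; the
sustained-attention (sATT) score is the fraction of analysed session time
spent in high-alert trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import Geometry, MetricParams
from .errors import NotBimodalError, UndefinedMetricError, ValidationError
from .metrics import local_path_reliability
from .session_io import TrialSlice

BC_THRESHOLD = 0.55


@dataclass
class BimodalityResult:
    bc: float
    skew: float
    kurt: float  # raw fourth standardised moment
    n: int

    @property
    def is_bimodal(self) -> bool:
        return self.bc > BC_THRESHOLD


@dataclass
class CutPoint:
    candidates: np.ndarray
    f_values: np.ndarray
    cut: float
    f_max: float


@dataclass
class StateClassification:
    bimodality: BimodalityResult
    cut: float | None
    labels: np.ndarray  # object array of 'high' / 'low' / None per trial
    satt: float | None
    high_time: float
    total_time: float
    episodes: pd.DataFrame | None


# ---------------------------------------------------------------------------
# Bimodality coefficient


def bimodality_coefficient(samples: np.ndarray) -> BimodalityResult:
    """Sample bimodality coefficient (finite-sample correction included)."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 4:
        raise ValidationError(f"bimodality coefficient needs n >= 4 samples, got {n}")
    m = x.mean()
    d = x - m
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValidationError("bimodality coefficient undefined for zero-variance samples")
    skew = np.mean(d**3) / m2**1.5
    kurt = np.mean(d**4) / m2**2
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    bc = (skew**2 + 1.0) / (kurt - 3.0 + corr)
    return BimodalityResult(bc=float(bc), skew=float(skew), kurt=float(kurt), n=n)


def mixture_bc_large_n(separation: float) -> float:
    """Large-n BC of an equal-weight mixture of two unit-SD normals.

    Modes sit at ±separation/2; the mixture is symmetric (skew 0) with raw
    kurtosis (3 + 1.5 d^2 + d^4/16) / (1 + d^2/4)^2, so BC -> 1/kurt.
    """
    d2 = separation**2
    kurt = (3.0 + 1.5 * d2 + d2**2 / 16.0) / (1.0 + d2 / 4.0) ** 2
    return 1.0 / kurt


def mixture_bc_crossing(bc_threshold: float = BC_THRESHOLD) -> float:
    """Mode separation (in component SD) where the large-n BC crosses the
    bimodality threshold, by root finding on the analytic mixture moments."""
    return float(brentq(lambda d: mixture_bc_large_n(d) - bc_threshold, 0.5, 20.0))


# ---------------------------------------------------------------------------
# Variance-ratio cut point


def find_cut_point(samples: np.ndarray) -> CutPoint:
    """Exhaustive variance-ratio scan over midpoints of sorted unique values.

    Requires at least two samples on each side of a candidate; ties on F
    resolve to the earliest (smallest) cut.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    x = x[~np.isnan(x)]
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValidationError("cut point undefined: all samples equal")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    var_all = x.var(ddof=1)
    cands, fs = [], []
    for c in mids:
        lo = x[x <= c]
        hi = x[x > c]
        if len(lo) < 2 or len(hi) < 2:
            continue
        denom = 0.5 * (lo.var(ddof=1) + hi.var(ddof=1))
        f = np.inf if denom == 0 else var_all / denom
        cands.append(c)
        fs.append(f)
    if not cands:
        raise ValidationError("cut point undefined: no candidate leaves >= 2 samples per side")
    cands = np.asarray(cands)
    fs = np.asarray(fs)
    best = int(np.argmax(fs))  # first maximum = earliest cut on ties
    return CutPoint(candidates=cands, f_values=fs, cut=float(cands[best]),
                    f_max=float(fs[best]))


# ---------------------------------------------------------------------------
# State labels and the sATT score


def classify_states(
    local_pr: np.ndarray, durations: np.ndarray
) -> StateClassification:
    """High/low-alert labels per trial plus the sATT score.

    Trials with undefined local PR stay unlabelled and contribute no time.
    Raises :class:`NotBimodalError` when the pooled distribution fails the
    BC > 0.55 criterion (states and sATT are then undefined for the animal).
    """
    local_pr = np.asarray(local_pr, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if len(local_pr) != len(durations):
        raise ValidationError("local_pr and durations must have equal length")
    defined = ~np.isnan(local_pr)
    bim = bimodality_coefficient(local_pr[defined])
    if not bim.is_bimodal:
        raise NotBimodalError(
            f"local-PR distribution is not bimodal (BC = {bim.bc:.3f} <= {BC_THRESHOLD}); "
            "alertness states and the sATT score are undefined for this animal"
        )
    cut = find_cut_point(local_pr[defined]).cut
    labels = np.full(len(local_pr), None, dtype=object)
    labels[defined & (local_pr > cut)] = "high"
    labels[defined & (local_pr <= cut)] = "low"
    high_time = float(durations[labels == "high"].sum())
    total_time = float(durations[defined].sum())
    satt = high_time / total_time if total_time > 0 else np.nan
    episodes = _episodes(labels, durations)
    return StateClassification(
        bimodality=bim, cut=cut, labels=labels, satt=satt,
        high_time=high_time, total_time=total_time, episodes=episodes,
    )


def _episodes(labels: np.ndarray, durations: np.ndarray) -> pd.DataFrame:
    """Contiguous same-label runs over the defined-label trial sequence."""
    rows = []
    current = None
    for i, lab in enumerate(labels):
        if lab is None:
            continue
        if current is None or current["state"] != lab:
            if current is not None:
                rows.append(current)
            current = {"state": lab, "start_trial": i, "end_trial": i,
                       "n_trials": 1, "duration": float(durations[i])}
        else:
            current["end_trial"] = i
            current["n_trials"] += 1
            current["duration"] += float(durations[i])
    if current is not None:
        rows.append(current)
    return pd.DataFrame(rows, columns=["state", "start_trial", "end_trial",
                                       "n_trials", "duration"])


# ---------------------------------------------------------------------------
# Controls and correlations


def error_reassignment_control(
    slices: list[TrialSlice],
    geom: Geometry,
    params: MetricParams,
    seed: int | np.random.Generator = 0,
) -> BimodalityResult:
    """BC after replacing every error trial's path with a same-side hit path.

    If the apparent local-PR bimodality were produced by isolated error
    trials in otherwise error-free stretches, it disappears under this
    reassignment; genuine state-driven path variability keeps BC > 0.55.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inc = [s for s in slices if s.include_flag]
    hits = {side: [s for s in inc if s.side == side and s.outcome == "target"]
            for side in ("left", "right")}
    reassigned: list[TrialSlice] = []
    for s in inc:
        if s.outcome == "target":
            reassigned.append(s)
            continue
        pool = hits[s.side]
        if not pool:
            raise UndefinedMetricError(
                f"no hit trials on side {s.side!r} available for reassignment"
            )
        donor = pool[int(rng.integers(len(pool)))]
        swapped = TrialSlice(
            trial_id=s.trial_id, side=s.side, delta_ori=s.delta_ori,
            cue_flag=s.cue_flag, cue_type=s.cue_type, outcome="target",
            repeat_flag=s.repeat_flag, onset=s.onset, offset=s.offset,
            shift_time=s.shift_time, time=s.time, x=donor.x, y=donor.y,
            lick=s.lick, sample_rate=s.sample_rate, include_flag=True,
        )
        reassigned.append(swapped)
    local = local_path_reliability(reassigned, geom, params)
    return bimodality_coefficient(local[~np.isnan(local)])


SMOOTHED_METRICS = (
    "hit_index", "target_distance", "reaction_time",
    "path_surplus", "lick_position", "running_speed",
)


def smoothed_metric_correlations(
    table: pd.DataFrame, window: int = 25
) -> dict[str, float]:
    """Pearson r between each smoothed primary metric and the local-PR trace.

    Each metric is smoothed with a centred ``window``-trial moving average
    over included trials; correlations run over trials where both the
    smoothed metric and local PR are defined.  Constant traces yield NaN.
    """
    sub = table[table["include_flag"]].reset_index(drop=True)
    if len(sub) < window:
        raise UndefinedMetricError(
            f"need at least {window} included trials, got {len(sub)}"
        )
    local = sub["local_pr"].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for m in SMOOTHED_METRICS:
        smoothed = (
            sub[m].rolling(window, center=True, min_periods=window).mean().to_numpy()
        )
        ok = ~np.isnan(smoothed) & ~np.isnan(local)
        if ok.sum() < 3:
            out[m] = float("nan")
            continue
        a, b = smoothed[ok], local[ok]
        if a.std() == 0 or b.std() == 0:
            out[m] = float("nan")
            continue
        out[m] = float(np.corrcoef(a, b)[0, 1])
    return out


__all__ = [
    "BC_THRESHOLD",
    "BimodalityResult",
    "CutPoint",
    "StateClassification",
    "bimodality_coefficient",
    "mixture_bc_large_n",
    "mixture_bc_crossing",
    "find_cut_point",
    "classify_states",
    "error_reassignment_control",
    "smoothed_metric_correlations",
    "SMOOTHED_METRICS",
]
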