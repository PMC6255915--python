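"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from vefkit.config import Geometry
from vefkit.session_io import TrialSlice


def path_slice(
    x_path,
    side: str = "left",
    outcome: str | None = None,
    fs: float = 60.0,
    speed: float = 16.0,
    geom: Geometry | None = None,
    trial_id: int = 0,
    licks: np.ndarray | None = None,
    include: bool = True,
    delta_ori: float = 90.0,
) -> TrialSlice:
    """A straight-forward trial slice with a prescribed lateral path.

    ``x_path`` is either a constant, an array of per-sample lateral
    positions, or a callable x(y).  The trial runs from start to the target
    row at constant forward speed; the shift fires at the trigger row.
    """
    geom = geom or Geometry()
    n = int(round((geom.target_y - geom.start_y) / speed * fs)) + 1
    y = np.linspace(geom.start_y, geom.target_y, n)
    if callable(x_path):
        x = np.asarray([x_path(v) for v in y], dtype=float)
    elif np.isscalar(x_path):
        x = np.full(n, float(x_path))
    else:
        x = np.asarray(x_path, dtype=float)
        n = len(x)
        y = np.linspace(geom.start_y, geom.target_y, n)
    t = np.arange(n) / fs
    shift_idx = int(np.searchsorted(y, geom.trigger_y))
    if outcome is None:
        x_m = x[-1]
        lo, hi = geom.wall_span(side)
        if lo <= x_m <= hi:
            outcome = "target"
        else:
            d = Geometry.distractor_side(side) if side != "centre" else None
            if d is not None:
                dlo, dhi = geom.wall_span(d)
                outcome = "distractor" if dlo <= x_m <= dhi else "neither"
            else:
                outcome = "neither"
    return TrialSlice(
        trial_id=trial_id,
        side=side,
        delta_ori=delta_ori,
        cue_flag=False,
        cue_type="none",
        outcome=outcome,
        repeat_flag=False,
        onset=0.0,
        offset=n / fs,
        shift_time=t[shift_idx],
        time=t,
        x=x,
        y=y,
        lick=np.zeros(n, dtype=int) if licks is None else np.asarray(licks, dtype=int),
        sample_rate=fs,
        include_flag=include,
    )


def naive_cohens_d_profile(left_paths, right_paths, y_grid, step):
    """Loop-based, formula-literal Cohen's D profile (test oracle).

    ``left_paths``/``right_paths`` are lists of (y, x) arrays; per grid bin
    the per-trial mean x is taken over samples with y in [y0, y0 + step).
    """
    import math

    def binned(y, x, y0):
        vals = [xv for yv, xv in zip(y, x) if y0 <= yv < y0 + step]
        return sum(vals) / len(vals) if vals else None

    profile = []
    for y0 in y_grid:
        a = [binned(y, x, y0) for (y, x) in left_paths]
        b = [binned(y, x, y0) for (y, x) in right_paths]
        a = [v for v in a if v is not None]
        b = [v for v in b if v is not None]
        n_l, n_r = len(a), len(b)
        if n_l < 2 or n_r < 2:
            profile.append(None)
            continue
        mean_a = sum(a) / n_l
        mean_b = sum(b) / n_r
        var_a = sum((v - mean_a) ** 2 for v in a) / (n_l - 1)
        var_b = sum((v - mean_b) ** 2 for v in b) / (n_r - 1)
        pooled = math.sqrt(((n_l - 1) * var_a + (n_r - 1) * var_b) / (n_l + n_r - 2))
        diff = abs(mean_a - mean_b)
        if pooled == 0:
            profile.append(0.0 if diff < 1e-12 else float("inf"))
        else:
            profile.append(diff / pooled)
    return profile


def naive_bimodality(values):
    """Moment-by-moment BC re-implementation (test oracle)."""
    import math

    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    skew = m3 / m2**1.5
    kurt = m4 / m2**2
    return (skew**2 + 1.0) / (kurt - 3.0 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


def naive_cut(values):
    """Exhaustive variance-ratio cut scan (test oracle)."""
    import statistics

    xs = sorted(values)
    uniq = sorted(set(xs))
    best_cut, best_f = None, -1.0
    for lo_v, hi_v in zip(uniq[:-1], uniq[1:]):
        c = (lo_v + hi_v) / 2.0
        lo = [v for v in xs if v <= c]
        hi = [v for v in xs if v > c]
        if len(lo) < 2 or len(hi) < 2:
            continue
        denom = (statistics.variance(lo) + statistics.variance(hi)) / 2.0
        f = float("inf") if denom == 0 else statistics.variance(xs) / denom
        if f > best_f:
            best_f, best_cut = f, c
    return best_cut, best_f
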