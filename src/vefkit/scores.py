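"""Composite performance scores and the study-style statistical contrasts.

* **Cognitive Load (CL) index** — per trial, 0.5·NR + 0.25·NT + 0.25·NP,
  where NR/NT/NP are reaction time, target distance and path surplus
  normalised by the 5th/95th percentiles of their overall distributions.
  Reaction time carries half the weight because it is the only speed
  measure, while target distance and path surplus are complementary
  accuracy measures.
* **cATT score** — (CL_noncued − CL_cued) / CL_all: the relative
  improvement of the CL index in cued trials.
* **EP (error-prediction) index** — mean of the normalised hit-versus-miss
  differences of reaction time, path surplus and lick position; positive
  when the animal behaves as if anticipating errors.
* **Dunn–Šidák correction** — alpha_corr = 1 − (1 − alpha)^(1/n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError, ValidationError

CL_WEIGHTS = {"reaction_time": 0.5, "target_distance": 0.25, "path_surplus": 0.25}
CL_METRICS = tuple(CL_WEIGHTS)
EP_COMPONENTS = ("reaction_time", "path_surplus", "lick_position")


# ---------------------------------------------------------------------------
# Normalisation and the CL index


def normalization_bounds(
    tables: list[pd.DataFrame] | pd.DataFrame,
    metrics: tuple[str, ...] = CL_METRICS,
    min_trials: int = 20,
) -> dict[str, tuple[float, float]]:
    """5th/95th percentiles of each metric over the pooled input dataset."""
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    pooled = pd.concat(tables, ignore_index=True)
    pooled = pooled[pooled["include_flag"]]
    bounds = {}
    for m in metrics:
        vals = pooled[m].dropna().to_numpy()
        if len(vals) < min_trials:
            raise UndefinedMetricError(
                f"{m}: need >= {min_trials} defined trials to normalise, got {len(vals)}"
            )
        m5, m95 = np.percentile(vals, [5, 95])
        if m5 == m95:
            raise ValidationError(f"{m}: degenerate spread (5th == 95th percentile)")
        bounds[m] = (float(m5), float(m95))
    return bounds


def cl_index(
    table: pd.DataFrame, bounds: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Per-trial normalised metrics and CL index (NaN where inputs are).

    Values outside [M5, M95] map outside [0, 1] and are deliberately left
    unclipped.
    """
    out = pd.DataFrame(index=table.index)
    cols = {}
    for m, short in zip(CL_METRICS, ("NR", "NT", "NP")):
        m5, m95 = bounds[m]
        cols[short] = (table[m] - m5) / (m95 - m5)
    out["NR"], out["NT"], out["NP"] = cols["NR"], cols["NT"], cols["NP"]
    out["CL"] = 0.5 * out["NR"] + 0.25 * out["NT"] + 0.25 * out["NP"]
    out["defined"] = out["CL"].notna() & table["include_flag"].to_numpy()
    out.loc[~out["defined"], "CL"] = np.nan
    return out


@dataclass
class CattScore:
    catt: float
    cl_noncued: float
    cl_cued: float
    cl_all: float
    n_cued: int
    n_noncued: int


def catt_score(
    cl: pd.DataFrame, cue_flags: np.ndarray, min_per_group: int = 10
) -> CattScore:
    """cATT = (CL_noncued − CL_cued) / CL_all over defined choice trials."""
    cue_flags = np.asarray(cue_flags, dtype=bool)
    defined = cl["defined"].to_numpy()
    vals = cl["CL"].to_numpy()
    c = defined & cue_flags
    nc = defined & ~cue_flags
    if c.sum() < min_per_group or nc.sum() < min_per_group:
        raise UndefinedMetricError(
            f"need >= {min_per_group} defined cued and non-cued trials, "
            f"got {int(c.sum())} / {int(nc.sum())}"
        )
    cl_c = float(vals[c].mean())
    cl_nc = float(vals[nc].mean())
    cl_all = float(vals[defined].mean())
    if cl_all == 0:
        raise ValidationError("cATT undefined: average CL index is zero")
    return CattScore(
        catt=(cl_nc - cl_c) / cl_all, cl_noncued=cl_nc, cl_cued=cl_c,
        cl_all=cl_all, n_cued=int(c.sum()), n_noncued=int(nc.sum()),
    )


# ---------------------------------------------------------------------------
# Error-prediction index


@dataclass
class EPIndex:
    components: dict  # name -> delta in [-1, 1] or None if undefined
    ep: float | None
    n_hit: int
    n_miss: int


def _normalized_difference(miss: np.ndarray, hit: np.ndarray) -> float | None:
    """(mean_miss − mean_hit) / (mean_miss + mean_hit) on a positive scale.

    Mixed-sign components (lick position, occasionally path surplus) are
    shifted so that the pooled minimum maps to zero before normalising;
    the shift is symmetric in the two groups, preserving antisymmetry
    under label swap.
    """
    pooled_min = min(miss.min(), hit.min())
    shift = -pooled_min if pooled_min < 0 else 0.0
    m = miss.mean() + shift
    h = hit.mean() + shift
    denom = m + h
    if denom == 0:
        return None
    return float((m - h) / denom)


def ep_index(table: pd.DataFrame, min_per_group: int = 5) -> EPIndex:
    """Normalised hit-vs-miss differences of RT, PS and lick position.

    Positive values indicate correct outcome prediction: slower reactions,
    less efficient paths and later (less anticipatory) licking on trials
    the animal is about to get wrong.
    """
    sub = table[table["include_flag"]]
    hit_mask = sub["hit_index"] == 1
    miss_mask = sub["hit_index"].isin([0, -1])
    comps: dict[str, float | None] = {}
    for m in EP_COMPONENTS:
        h = sub.loc[hit_mask, m].dropna().to_numpy()
        mi = sub.loc[miss_mask, m].dropna().to_numpy()
        if len(h) < min_per_group or len(mi) < min_per_group:
            comps[m] = None
            continue
        comps[m] = _normalized_difference(mi, h)
    defined = [v for v in comps.values() if v is not None]
    return EPIndex(
        components=comps,
        ep=float(np.mean(defined)) if defined else None,
        n_hit=int(hit_mask.sum()),
        n_miss=int(miss_mask.sum()),
    )


# ---------------------------------------------------------------------------
# Statistics


def dunn_sidak(alpha: float, n_comparisons: int) -> float:
    """alpha_corr = 1 − (1 − alpha)^(1/n)."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if n_comparisons < 1:
        raise ValidationError(f"n_comparisons must be >= 1, got {n_comparisons}")
    return 1.0 - (1.0 - alpha) ** (1.0 / n_comparisons)


@dataclass
class Contrast:
    name: str
    t: float | None
    df: int | None
    p: float | None
    mean_diff: float | None
    sd_diff: float | None
    significant: bool | None
    alpha_corrected: float
    reason: str = ""


def state_cue_contrasts(
    summaries: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    zero_tests: list[str] | None = None,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    min_animals: int = 3,
) -> list[Contrast]:
    """Paired t-tests of per-animal condition summaries (+ one-sample tests).

    ``summaries`` has one row per animal and one column per condition;
    ``contrasts`` lists (condition_a, condition_b) pairs tested with a
    dependent-samples t-test; ``zero_tests`` lists columns (e.g. correlation
    coefficients) tested against zero.  Significance flags use the
    Dunn–Šidák-corrected alpha across all comparisons run.
    """
    zero_tests = zero_tests or []
    n_comp = n_comparisons if n_comparisons is not None else len(contrasts) + len(zero_tests)
    n_comp = max(n_comp, 1)
    a_corr = dunn_sidak(alpha, n_comp)
    out: list[Contrast] = []

    def run(name: str, values: np.ndarray) -> None:
        values = values[~np.isnan(values)]
        if len(values) < min_animals:
            out.append(Contrast(name=name, t=None, df=None, p=None,
                                mean_diff=None, sd_diff=None, significant=None,
                                alpha_corrected=a_corr,
                                reason=f"only {len(values)} animals (< {min_animals})"))
            return
        if np.allclose(values.std(ddof=1), 0.0):
            t_stat, p = (0.0, 1.0) if np.allclose(values.mean(), 0.0) else (np.inf, 0.0)
        else:
            t_stat, p = stats.ttest_1samp(values, 0.0)
        out.append(Contrast(name=name, t=float(t_stat), df=len(values) - 1,
                            p=float(p), mean_diff=float(values.mean()),
                            sd_diff=float(values.std(ddof=1)),
                            significant=bool(p < a_corr), alpha_corrected=a_corr))

    for cond_a, cond_b in contrasts:
        diff = (summaries[cond_a] - summaries[cond_b]).to_numpy(dtype=float)
        run(f"{cond_a} - {cond_b}", diff)
    for col in zero_tests:
        run(f"{col} vs 0", summaries[col].to_numpy(dtype=float))
    return out


__all__ = [
    "CL_WEIGHTS",
    "CL_METRICS",
    "EP_COMPONENTS",
    "normalization_bounds",
    "cl_index",
    "CattScore",
    "catt_score",
    "EPIndex",
    "ep_index",
    "dunn_sidak",
    "Contrast",
    "state_cue_contrasts",
]
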