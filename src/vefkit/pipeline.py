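"""End-to-end pipeline: simulate/load -> validate -> metrics -> thresholds
-> alertness states -> composite scores, with a reproducibility manifest.

All randomness flows from a single master seed, split per stage with
``numpy.random.SeedSequence`` so that stages stay deterministic under
reruns and independent of each other.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import Geometry, MetricParams, SimConfig, config_to_dict
from .errors import NotBimodalError, UndefinedMetricError, VefError
from .metrics import compute_metric_table, write_metric_table
from .psychometrics import DEFAULT_CRITERIA, threshold_by_condition
from .scores import catt_score, cl_index, ep_index, normalization_bounds
from .session_io import SessionData, read_session, segment_trials, write_session
from .states import classify_states, smoothed_metric_correlations
from .synthetic import generate_session, write_ground_truth

log = logging.getLogger("vefkit")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one session source)."""

    sim: SimConfig | None = None
    session_dir: str | Path | None = None
    geometry: Geometry | None = None
    params: MetricParams = field(default_factory=MetricParams)
    criteria: dict = field(default_factory=lambda: dict(DEFAULT_CRITERIA))
    out_dir: str | Path = "vef_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.session_dir is None):
            raise VefError("provide exactly one of sim config or session_dir")


def _config_hash(cfg: RunConfig) -> str:
    payload = {
        "sim": config_to_dict(cfg.sim) if cfg.sim else None,
        "session_dir": str(cfg.session_dir) if cfg.session_dir else None,
        "geometry": config_to_dict(cfg.geometry) if cfg.geometry else None,
        "params": config_to_dict(cfg.params),
        "criteria": cfg.criteria,
        "seed": cfg.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, write all artefacts, return the report dict."""
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    manifest: dict = {
        "vefkit_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
    }
    report: dict = {"seed": cfg.seed}

    def stage(name):
        t0 = _time.perf_counter()
        log.info("stage %s ...", name)
        return t0

    def done(name, t0, **counts):
        manifest["stages"][name] = {"seconds": round(_time.perf_counter() - t0, 3), **counts}

    # --- session -------------------------------------------------------------
    t0 = stage("session")
    if cfg.sim is not None:
        sim = cfg.sim
        session, truth = generate_session(sim)
        write_session(session, out_dir / "session")
        write_ground_truth(truth, out_dir / "session")
    else:
        session = read_session(cfg.session_dir)
    geom = cfg.geometry or session.geometry
    done("session", t0, n_trials=len(session.events), n_samples=len(session.trace))

    # --- metrics -------------------------------------------------------------
    t0 = stage("metrics")
    slices = segment_trials(session)
    table = compute_metric_table(session, geom, cfg.params)
    write_metric_table(table, out_dir / "metrics.tsv")
    done("metrics", t0, n_rows=len(table),
         n_included=int(table["include_flag"].sum()))

    # --- psychometrics -------------------------------------------------------
    t0 = stage("psychometrics")
    masks = {"all": np.ones(len(table), dtype=bool)}
    if table["cue_flag"].any():
        masks["cued"] = table["cue_flag"].to_numpy()
        masks["noncued"] = ~table["cue_flag"].to_numpy()
    thresholds = threshold_by_condition(
        table, masks, criteria=cfg.criteria, slices=slices,
        geometry=geom, params=cfg.params,
    )
    thr_rows = [
        {"condition": est.condition, "n_trials": est.n_trials,
         "averaged": est.averaged,
         **{f"thr_{k}": v for k, v in est.per_metric.items()}}
        for est in thresholds.values()
    ]
    pd.DataFrame(thr_rows).to_csv(out_dir / "thresholds.tsv", sep="\t", index=False)
    report["thresholds"] = {
        name: {"per_metric": est.per_metric, "averaged": est.averaged,
               "n_trials": est.n_trials}
        for name, est in thresholds.items()
    }
    done("psychometrics", t0, n_conditions=len(thresholds))

    # --- alertness states ----------------------------------------------------
    t0 = stage("states")
    inc = table[table["include_flag"]]
    try:
        classification = classify_states(
            inc["local_pr"].to_numpy(), inc["duration"].to_numpy()
        )
        report["states"] = {
            "bc": classification.bimodality.bc,
            "cut": classification.cut,
            "satt": classification.satt,
            "high_time": classification.high_time,
            "total_time": classification.total_time,
            "n_episodes": len(classification.episodes),
        }
        labels = pd.Series(classification.labels, index=inc.index)
        state_col = pd.Series("undefined", index=table.index, dtype=object)
        state_col.loc[inc.index] = labels.map(lambda v: v if v else "undefined")
        states_out = table[["trial_id", "include_flag", "local_pr", "duration"]].copy()
        states_out["state"] = state_col
        states_out.to_csv(out_dir / "states.tsv", sep="\t", index=False,
                          float_format="%.6f", na_rep="NA")
    except (NotBimodalError, VefError) as exc:
        classification = None
        report["states"] = {"undefined_reason": str(exc)}
    try:
        report["metric_correlations"] = smoothed_metric_correlations(table)
    except UndefinedMetricError as exc:
        report["metric_correlations"] = {"undefined_reason": str(exc)}
    done("states", t0)

    # --- composite scores ----------------------------------------------------
    t0 = stage("scores")
    try:
        bounds = normalization_bounds(table)
        cl = cl_index(table, bounds)
        report["cl"] = {
            "bounds": {k: list(v) for k, v in bounds.items()},
            "mean": float(cl["CL"].mean()),
            "n_defined": int(cl["defined"].sum()),
        }
        if classification is not None:
            state_arr = report_state_series(table, classification)
            for label in ("high", "low"):
                vals = cl.loc[(state_arr == label) & cl["defined"], "CL"]
                report["cl"][f"mean_{label}"] = float(vals.mean()) if len(vals) else None
        if table["cue_flag"].any():
            catt = catt_score(cl, table["cue_flag"].to_numpy())
            report["catt"] = {
                "catt": catt.catt, "cl_cued": catt.cl_cued,
                "cl_noncued": catt.cl_noncued, "cl_all": catt.cl_all,
            }
    except (UndefinedMetricError, VefError) as exc:
        report["cl"] = {"undefined_reason": str(exc)}
    ep = ep_index(table)
    report["ep"] = {"components": ep.components, "ep": ep.ep,
                    "n_hit": ep.n_hit, "n_miss": ep.n_miss}
    done("scores", t0)

    manifest["stage_seeds"] = stage_seed
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def report_state_series(table: pd.DataFrame, classification) -> pd.Series:
    """Per-row high/low/undefined labels aligned with the full metric table."""
    out = pd.Series("undefined", index=table.index, dtype=object)
    inc_idx = table.index[table["include_flag"]]
    for i, lab in zip(inc_idx, classification.labels):
        if lab is not None:
            out.loc[i] = lab
    return out


__all__ = ["RunConfig", "run_pipeline", "report_state_series"]
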