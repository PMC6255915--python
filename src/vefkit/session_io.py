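"""Session file dialect, validation, and trial segmentation.

A session is stored as two UTF-8 tab-separated files with one header row:

``events.tsv`` — one row per trial
    trial_id, onset, offset, shift_time, side, delta_ori, cue_flag,
    cue_type, outcome, reward_ul, repeat_flag

``trace.tsv`` — the continuous 60 Hz behavioural readout
    time, x, y, fwd, lat, lick

Times are seconds from session start; ``x``/``y`` are virtual-arena
coordinates in cm; ``fwd``/``lat`` are treadmill displacement per sample in
cm; ``lick`` is 1 on samples with lick-sensor contact.  Trial-relative times
are always computed, never stored, and sample selection at trial boundaries
is half-open: a trial owns samples with ``onset <= time < offset``.

Missing values (``delta_ori`` on centre trials) are written as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .config import Geometry, SIDES, geometry_from_dict, config_to_dict
from .errors import ValidationError

EVENT_COLUMNS = [
    "trial_id", "onset", "offset", "shift_time", "side", "delta_ori",
    "cue_flag", "cue_type", "outcome", "reward_ul", "repeat_flag",
]
TRACE_COLUMNS = ["time", "x", "y", "fwd", "lat", "lick"]
OUTCOMES = ("target", "distractor", "neither")
FLOAT_FORMAT = "%.6f"


@dataclass
class EventLog:
    """Typed per-trial event table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.table.columns]
        extra = [c for c in self.table.columns if c not in EVENT_COLUMNS]
        if missing or extra:
            raise ValidationError(
                f"events: missing columns {missing}, unexpected columns {extra}"
            )
        t = self.table
        ids = t["trial_id"].to_numpy()
        if len(ids) and not np.all(np.diff(ids) > 0):
            row = int(np.flatnonzero(np.diff(ids) <= 0)[0]) + 1
            raise ValidationError(f"events row {row}: trial_id not strictly increasing")
        bad_side = ~t["side"].isin(SIDES)
        if bad_side.any():
            row = int(np.flatnonzero(bad_side.to_numpy())[0])
            raise ValidationError(f"events row {row}: unknown side {t['side'].iloc[row]!r}")
        bad_out = ~t["outcome"].isin(OUTCOMES)
        if bad_out.any():
            row = int(np.flatnonzero(bad_out.to_numpy())[0])
            raise ValidationError(f"events row {row}: unknown outcome {t['outcome'].iloc[row]!r}")
        choice = t["side"] != "centre"
        bad = choice & ~((t["onset"] < t["shift_time"]) & (t["shift_time"] < t["offset"]))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"events row {row}: requires onset < shift_time < offset for choice trials"
            )
        centre_distract = (t["side"] == "centre") & (t["outcome"] == "distractor")
        if centre_distract.any():
            row = int(np.flatnonzero(centre_distract.to_numpy())[0])
            raise ValidationError(f"events row {row}: centre trial cannot touch a distractor")

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and self.table.equals(other.table)


@dataclass
class ContinuousTrace:
    """Continuous 60 Hz behavioural readout."""

    table: pd.DataFrame
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.table.columns]
        extra = [c for c in self.table.columns if c not in TRACE_COLUMNS]
        if missing or extra:
            raise ValidationError(
                f"trace: missing columns {missing}, unexpected columns {extra}"
            )
        t = self.table["time"].to_numpy()
        if len(t) >= 2:
            steps = np.diff(t)
            nominal = 1.0 / self.sample_rate
            bad = (steps <= 0) | (np.abs(steps - nominal) > 0.1 * nominal)
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 1
                raise ValidationError(
                    f"trace row {row}: time step {steps[row - 1]:.6f}s is not "
                    f"within 10% of the nominal {nominal:.6f}s (or not increasing)"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    def __eq__(self, other) -> bool:
        return isinstance(other, ContinuousTrace) and self.table.equals(other.table)


@dataclass
class SessionData:
    """One recorded (or simulated) session."""

    events: EventLog
    trace: ContinuousTrace
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trace) == 0:
            raise ValidationError("trace is empty")
        t0, t1 = self.trace.time[0], self.trace.time[-1]
        ev = self.events.table
        out = (ev["onset"] < t0 - 1e-9) | (ev["offset"] > t1 + 1.5 / self.trace.sample_rate)
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise ValidationError(
                f"events row {row}: trial interval [{ev['onset'].iloc[row]}, "
                f"{ev['offset'].iloc[row]}) lies outside the trace time span"
            )

    @property
    def geometry(self) -> Geometry:
        g = self.metadata.get("geometry")
        if isinstance(g, Geometry):
            return g
        if isinstance(g, dict):
            return geometry_from_dict(g)
        return Geometry()


@dataclass
class TrialSlice:
    """One trial's trace segment plus labels, re-anchored to the target shift."""

    trial_id: int
    side: str
    delta_ori: float
    cue_flag: bool
    cue_type: str
    outcome: str
    repeat_flag: bool
    onset: float
    offset: float
    shift_time: float
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lick: np.ndarray
    sample_rate: float
    include_flag: bool

    @property
    def t_rel(self) -> np.ndarray:
        """Sample times relative to the target shift."""
        return self.time - self.shift_time

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"{name} file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"{path}: cannot parse ({exc})") from exc


def read_events(path: str | Path) -> EventLog:
    df = _read_tsv(Path(path), "events")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[EVENT_COLUMNS].copy()
    df["trial_id"] = df["trial_id"].astype(int)
    for col in ("cue_flag", "repeat_flag"):
        df[col] = df[col].astype(int).astype(bool)
    for col in ("onset", "offset", "shift_time", "delta_ori", "reward_ul"):
        df[col] = pd.to_numeric(df[col])
    return EventLog(df.reset_index(drop=True))


def read_continuous(path: str | Path, sample_rate: float = 60.0) -> ContinuousTrace:
    df = _read_tsv(Path(path), "trace")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[TRACE_COLUMNS].copy()
    for col in TRACE_COLUMNS:
        df[col] = pd.to_numeric(df[col])
    df["lick"] = df["lick"].astype(int)
    return ContinuousTrace(df.reset_index(drop=True), sample_rate=sample_rate)


def read_session(directory: str | Path) -> SessionData:
    directory = Path(directory)
    metadata: dict = {}
    meta_path = directory / "metadata.yaml"
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = yaml.safe_load(fh) or {}
    sample_rate = float(metadata.get("sample_rate", 60.0))
    events = read_events(directory / "events.tsv")
    trace = read_continuous(directory / "trace.tsv", sample_rate=sample_rate)
    return SessionData(events, trace, metadata)


def write_session(session: SessionData, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ev = session.events.table.copy()
    for col in ("cue_flag", "repeat_flag"):
        ev[col] = ev[col].astype(int)
    ev.to_csv(directory / "events.tsv", sep="\t", index=False,
              float_format=FLOAT_FORMAT, na_rep="NA")
    session.trace.table.to_csv(directory / "trace.tsv", sep="\t", index=False,
                               float_format=FLOAT_FORMAT, na_rep="NA")
    metadata = dict(session.metadata)
    geom = metadata.get("geometry")
    if isinstance(geom, Geometry):
        metadata["geometry"] = config_to_dict(geom)
    metadata.setdefault("sample_rate", session.trace.sample_rate)
    with open(directory / "metadata.yaml", "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Segmentation


def segment_trials(session: SessionData) -> list[TrialSlice]:
    """Cut the continuous trace into one slice per event-log trial.

    Sample ownership is half-open (``onset <= t < offset``); a slice is
    flagged for analysis inclusion only when the trial is a non-repeat
    left/right choice trial.
    """
    t = session.trace.time
    tbl = session.trace.table
    x = tbl["x"].to_numpy()
    y = tbl["y"].to_numpy()
    lick = tbl["lick"].to_numpy()
    slices = []
    for row in session.events.table.itertuples(index=False):
        i0 = int(np.searchsorted(t, row.onset - 1e-9, side="left"))
        i1 = int(np.searchsorted(t, row.offset - 1e-9, side="left"))
        if i1 <= i0:
            raise ValidationError(f"trial {row.trial_id}: no trace samples in [onset, offset)")
        include = (not row.repeat_flag) and row.side in ("left", "right")
        slices.append(
            TrialSlice(
                trial_id=int(row.trial_id),
                side=row.side,
                delta_ori=float(row.delta_ori) if pd.notna(row.delta_ori) else float("nan"),
                cue_flag=bool(row.cue_flag),
                cue_type=row.cue_type,
                outcome=row.outcome,
                repeat_flag=bool(row.repeat_flag),
                onset=float(row.onset),
                offset=float(row.offset),
                shift_time=float(row.shift_time),
                time=t[i0:i1],
                x=x[i0:i1],
                y=y[i0:i1],
                lick=lick[i0:i1],
                sample_rate=session.trace.sample_rate,
                include_flag=include,
            )
        )
    return slices


def included(slices: list[TrialSlice]) -> list[TrialSlice]:
    return [s for s in slices if s.include_flag]


__all__ = [
    "EventLog",
    "ContinuousTrace",
    "SessionData",
    "TrialSlice",
    "read_events",
    "read_continuous",
    "read_session",
    "write_session",
    "segment_trials",
    "included",
    "EVENT_COLUMNS",
    "TRACE_COLUMNS",
]
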