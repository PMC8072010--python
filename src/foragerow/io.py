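"""Reading and writing session bundles.

Two on-disk formats are supported (documented in ``docs/SCHEMA.md``):

``csv_bundle``
    A directory with ``sessions.csv`` (session-level fields), ``trials.csv``
    (one row per trial, scalar fields only), ``trajectories.csv``
    (participant_id, trial_index, t_ms, x, y, heading_deg) and
    ``magazine.csv`` (participant_id, zone_id, t_start_ms, duration_ms).

``jsonl``
    One JSON object per line, each a whole session with embedded trials,
    trajectories and magazine events.

All numeric result tables produced by the pipeline are written as TSV with a
leading ``#`` comment line that records the package version and a hash of the
run configuration, so any table can be traced back to the code and settings
that produced it.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .session import (
    BeamBreak,
    SchemaError,
    Session,
    Trajectory,
    TrialRecord,
    ValidationError,
    truncate_reentry,
    validate_session,
)

__all__ = ["read_sessions", "write_sessions", "write_tsv", "read_tsv", "config_hash"]

SESSIONS_COLS = [
    "participant_id", "task_variant", "version", "setting",
    "gender", "age", "bmi_group", "smoker",
]
TRIALS_COLS = [
    "participant_id", "trial_index", "zone_id", "category", "offered_delay_s",
    "decision", "t_offer_ms", "t_move_ms", "t_exit_ms", "t_delay_start_ms",
    "t_quit_or_complete_ms", "entry_position",
]
TRAJ_COLS = ["participant_id", "trial_index", "t_ms", "x", "y", "heading_deg"]
MAG_COLS = ["participant_id", "zone_id", "t_start_ms", "duration_ms"]

_COVARIATE_KEYS = ("gender", "age", "bmi_group", "smoker")


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return int(v)


# ---------------------------------------------------------------------------
# csv_bundle


def _sessions_to_frames(sessions: Sequence[Session]):
    srows, trows, prows, mrows = [], [], [], []
    for s in sessions:
        cov = s.covariates
        srows.append([
            s.participant_id, s.task_variant, s.version, s.setting,
            cov.get("gender"), cov.get("age"), cov.get("bmi_group"), cov.get("smoker"),
        ])
        for tr in s.trials:
            trows.append([
                s.participant_id, tr.trial_index, tr.zone_id, tr.category,
                tr.offered_delay, tr.decision, tr.t_offer, tr.t_move, tr.t_exit,
                tr.t_delay_start, tr.t_quit_or_complete, tr.entry_position,
            ])
            if tr.trajectory is not None and len(tr.trajectory):
                traj = tr.trajectory
                block = np.column_stack([traj.t, traj.x, traj.y, traj.heading])
                prows.append((s.participant_id, tr.trial_index, block))
        for ev in s.magazine_events:
            mrows.append([s.participant_id, ev.zone_id, ev.t_start, ev.duration])
    sess_df = pd.DataFrame(srows, columns=SESSIONS_COLS)
    trial_df = pd.DataFrame(trows, columns=TRIALS_COLS)
    if prows:
        parts = []
        for pid, idx, block in prows:
            d = pd.DataFrame(block, columns=["t_ms", "x", "y", "heading_deg"])
            d.insert(0, "trial_index", idx)
            d.insert(0, "participant_id", pid)
            parts.append(d)
        traj_df = pd.concat(parts, ignore_index=True)
    else:
        traj_df = pd.DataFrame(columns=TRAJ_COLS)
    mag_df = pd.DataFrame(mrows, columns=MAG_COLS)
    return sess_df, trial_df, traj_df, mag_df


def _require_cols(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required column(s) {missing}")


def _read_csv_bundle(path: Path) -> list[Session]:
    # round_trip float parsing keeps write -> read -> write byte-stable
    rc = dict(float_precision="round_trip")
    sess_df = pd.read_csv(path / "sessions.csv", **rc)
    trial_df = pd.read_csv(path / "trials.csv", **rc)
    _require_cols(sess_df, SESSIONS_COLS[:4], "sessions.csv")
    _require_cols(trial_df, TRIALS_COLS, "trials.csv")
    traj_path = path / "trajectories.csv"
    traj_df = pd.read_csv(traj_path, **rc) if traj_path.exists() else pd.DataFrame(columns=TRAJ_COLS)
    mag_path = path / "magazine.csv"
    mag_df = pd.read_csv(mag_path, **rc) if mag_path.exists() else pd.DataFrame(columns=MAG_COLS)
    if len(traj_df):
        _require_cols(traj_df, TRAJ_COLS, "trajectories.csv")
    if len(mag_df):
        _require_cols(mag_df, MAG_COLS, "magazine.csv")

    traj_groups = dict(tuple(traj_df.groupby(["participant_id", "trial_index"]))) if len(traj_df) else {}
    mag_groups = dict(tuple(mag_df.groupby("participant_id"))) if len(mag_df) else {}
    trial_groups = dict(tuple(trial_df.groupby("participant_id", sort=False)))

    sessions = []
    for _, srow in sess_df.iterrows():
        pid = srow["participant_id"]
        cov = {k: srow.get(k) for k in _COVARIATE_KEYS if pd.notna(srow.get(k))}
        sess = Session(
            participant_id=str(pid),
            task_variant=str(srow["task_variant"]),
            version=int(srow["version"]),
            setting=str(srow["setting"]),
            covariates=cov,
        )
        tdf = trial_groups.get(pid)
        if tdf is not None:
            for _, r in tdf.sort_values("trial_index").iterrows():
                idx = int(r["trial_index"])
                traj = None
                g = traj_groups.get((pid, idx))
                if g is not None:
                    traj = Trajectory(
                        g["t_ms"].to_numpy(float), g["x"].to_numpy(float),
                        g["y"].to_numpy(float), g["heading_deg"].to_numpy(float),
                    )
                sess.trials.append(TrialRecord(
                    trial_index=idx,
                    zone_id=int(r["zone_id"]),
                    category=str(r["category"]),
                    offered_delay=float(r["offered_delay_s"]),
                    decision=str(r["decision"]),
                    t_offer=int(r["t_offer_ms"]),
                    t_exit=int(r["t_exit_ms"]),
                    t_move=_opt_int(r["t_move_ms"]),
                    t_delay_start=_opt_int(r["t_delay_start_ms"]),
                    t_quit_or_complete=_opt_int(r["t_quit_or_complete_ms"]),
                    entry_position=float(r["entry_position"]),
                    trajectory=traj,
                ))
        g = mag_groups.get(pid)
        if g is not None:
            for _, r in g.iterrows():
                sess.magazine_events.append(BeamBreak(
                    int(r["zone_id"]), int(r["t_start_ms"]), int(r["duration_ms"])))
        sessions.append(sess)
    return sessions


def _write_csv_bundle(sessions: Sequence[Session], path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    sess_df, trial_df, traj_df, mag_df = _sessions_to_frames(sessions)
    sess_df.to_csv(path / "sessions.csv", index=False)
    trial_df.to_csv(path / "trials.csv", index=False)
    traj_df.to_csv(path / "trajectories.csv", index=False)
    mag_df.to_csv(path / "magazine.csv", index=False)


# ---------------------------------------------------------------------------
# jsonl


def _session_to_obj(s: Session) -> dict:
    def trial_obj(tr: TrialRecord) -> dict:
        d = {
            "trial_index": tr.trial_index, "zone_id": tr.zone_id,
            "category": tr.category, "offered_delay": tr.offered_delay,
            "decision": tr.decision, "t_offer": tr.t_offer, "t_exit": tr.t_exit,
            "t_move": tr.t_move, "t_delay_start": tr.t_delay_start,
            "t_quit_or_complete": tr.t_quit_or_complete,
            "entry_position": tr.entry_position,
        }
        if tr.trajectory is not None and len(tr.trajectory):
            traj = tr.trajectory
            d["trajectory"] = {
                "t": traj.t.tolist(), "x": traj.x.tolist(),
                "y": traj.y.tolist(), "heading": traj.heading.tolist(),
            }
        return d

    return {
        "participant_id": s.participant_id,
        "task_variant": s.task_variant,
        "version": s.version,
        "setting": s.setting,
        "covariates": s.covariates,
        "trials": [trial_obj(t) for t in s.trials],
        "magazine_events": [
            {"zone_id": e.zone_id, "t_start": e.t_start, "duration": e.duration}
            for e in s.magazine_events
        ],
    }


def _session_from_obj(obj: dict) -> Session:
    for key in ("participant_id", "task_variant", "version", "setting", "trials"):
        if key not in obj:
            raise SchemaError(f"jsonl session object missing field {key!r}")
    sess = Session(
        participant_id=str(obj["participant_id"]),
        task_variant=obj["task_variant"],
        version=int(obj["version"]),
        setting=obj["setting"],
        covariates=dict(obj.get("covariates") or {}),
    )
    for t in obj["trials"]:
        traj = None
        if t.get("trajectory"):
            tt = t["trajectory"]
            traj = Trajectory(np.asarray(tt["t"], float), np.asarray(tt["x"], float),
                              np.asarray(tt["y"], float), np.asarray(tt["heading"], float))
        sess.trials.append(TrialRecord(
            trial_index=int(t["trial_index"]), zone_id=int(t["zone_id"]),
            category=t["category"], offered_delay=float(t["offered_delay"]),
            decision=t["decision"], t_offer=int(t["t_offer"]), t_exit=int(t["t_exit"]),
            t_move=_opt_int(t.get("t_move")),
            t_delay_start=_opt_int(t.get("t_delay_start")),
            t_quit_or_complete=_opt_int(t.get("t_quit_or_complete")),
            entry_position=float(t.get("entry_position", 0.0)),
            trajectory=traj,
        ))
    for e in obj.get("magazine_events", []):
        sess.magazine_events.append(BeamBreak(int(e["zone_id"]), int(e["t_start"]), int(e["duration"])))
    return sess


# ---------------------------------------------------------------------------
# public interface


def read_sessions(path, format: str = "csv_bundle", on_invalid: str = "raise") -> list[Session]:
    """Read and validate sessions from disk.

    Parameters
    ----------
    path : directory (csv_bundle) or file (jsonl)
    format : {"csv_bundle", "jsonl"}
    on_invalid : {"raise", "drop"}
        ``raise`` (default) raises :class:`ValidationError` listing every
        violating trial; ``drop`` removes violating trials and attaches the
        report to the returned sessions' ``covariates["_validation_report"]``.
    """
    path = Path(path)
    if format == "csv_bundle":
        sessions = _read_csv_bundle(path)
    elif format == "jsonl":
        sessions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    sessions.append(_session_from_obj(json.loads(line)))
    else:
        raise ValueError(f"unknown format {format!r}")

    for s in sessions:
        s.trials = [truncate_reentry(t) for t in s.trials]

    report: list[str] = []
    for s in sessions:
        problems = validate_session(s)
        if not problems:
            continue
        if on_invalid == "raise":
            msg = "; ".join(problems)
            raise ValidationError(f"session {s.participant_id}: {msg}")
        bad = {int(p.split()[1].rstrip(":")) for p in problems if p.startswith("trial ")}
        report.extend(f"{s.participant_id}: {p}" for p in problems)
        s.trials = [t for t in s.trials if t.trial_index not in bad]
        for new_idx, t in enumerate(s.trials):
            t.trial_index = new_idx
    if on_invalid == "drop" and report:
        for s in sessions:
            s.covariates["_validation_report"] = report
    return sessions


def write_sessions(sessions: Sequence[Session], path, format: str = "csv_bundle"):
    """Write sessions so that :func:`read_sessions` round-trips losslessly."""
    path = Path(path)
    if format == "csv_bundle":
        _write_csv_bundle(sessions, path)
    elif format == "jsonl":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for s in sessions:
                fh.write(json.dumps(_session_to_obj(s)) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# TSV result tables


def config_hash(config) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, config=None) -> Path:
    """Write a result table as TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config or {})
    with open(path, "w") as fh:
        fh.write(f"# foragerow {__version__} config={chash}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
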