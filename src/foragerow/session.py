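"""Canonical data model for foraging-task sessions.

A session is one participant's run through a virtual square track with four
reward zones. At each zone the participant receives an offer (a reward
category plus a delay in seconds) inside an *offer zone* and decides to stay
(wait out the delay for the reward), skip, or — after starting the delay —
quit. The types here hold the per-trial event timestamps, the offer-zone
trajectory samples used for vicarious trial-and-error (VTE) measures, and,
for the food-reward task variant, the infrared beam-break log of the candy
magazines.

Time base: all timestamps are integer-valued milliseconds from session start;
offered delays are seconds as floats. Trial indices are 0-based and zone ids
run 0-3 around the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DECISIONS",
    "TASK_VARIANTS",
    "Trajectory",
    "TrialRecord",
    "BeamBreak",
    "Session",
    "SchemaError",
    "ValidationError",
    "validate_trial",
    "validate_session",
    "score_magazine_retrievals",
]

DECISIONS = ("stay", "skip", "quit")
TASK_VARIANTS = ("movie", "candy")
SETTINGS = ("in_person", "online")

#: Beam breaks scored as a reward retrieval must last between these bounds
#: (both inclusive).
RETRIEVAL_MIN_MS = 50
RETRIEVAL_MAX_MS = 10_000
#: Magazine analysis is restricted to the first 20 minutes of the session.
MAGAZINE_WINDOW_MS = 20 * 60 * 1000


class SchemaError(Exception):
    """A file is missing required columns or fields."""


class ValidationError(Exception):
    """Data violates an invariant of the session model."""


@dataclass
class Trajectory:
    """Ordered (t, x, y, heading) samples within one offer-zone visit.

    ``t`` is milliseconds from session start and must be strictly increasing;
    ``heading`` is the facing direction in degrees within [0, 360). Positions
    are in arbitrary track units.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)

    def __len__(self) -> int:
        return len(self.t)

    def problems(self) -> list[str]:
        out = []
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.heading) == n):
            out.append("trajectory arrays have unequal lengths")
            return out
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            out.append("trajectory timestamps not strictly increasing")
        if n and (np.any(self.heading < 0) or np.any(self.heading >= 360)):
            out.append("heading outside [0, 360)")
        return out


@dataclass
class TrialRecord:
    """One offer: category, delay, decision and the associated events.

    ``entry_position`` is the lateral position on entering the offer zone as a
    signed fraction of the hallway width in [-0.5, +0.5]; negative is toward
    the participant's left and the reward location. ``t_move`` (first
    movement) exists only in task versions 3-4, which gate the avatar until
    the offer is presented. The trajectory covers the offer-zone pass up to
    the first exit; behavior after re-entry is never included.
    """

    trial_index: int
    zone_id: int
    category: str
    offered_delay: float
    decision: str
    t_offer: int
    t_exit: int
    t_move: Optional[int] = None
    t_delay_start: Optional[int] = None
    t_quit_or_complete: Optional[int] = None
    entry_position: float = 0.0
    trajectory: Optional[Trajectory] = None

    @property
    def waited_s(self) -> Optional[float]:
        """Time spent waiting after the delay countdown started, in seconds."""
        if self.t_delay_start is None or self.t_quit_or_complete is None:
            return None
        return (self.t_quit_or_complete - self.t_delay_start) / 1000.0

    @property
    def choice(self) -> int:
        """Stay coded 1; skip and quit coded 0."""
        return 1 if self.decision == "stay" else 0


@dataclass
class BeamBreak:
    """One break of a candy-magazine infrared beam."""

    zone_id: int
    t_start: int
    duration: int  # ms, > 0


@dataclass
class Session:
    participant_id: str
    task_variant: str = "movie"
    version: int = 2
    setting: str = "in_person"
    trials: list[TrialRecord] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)
    magazine_events: list[BeamBreak] = field(default_factory=list)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# Validation


def validate_trial(trial: TrialRecord, version: int) -> list[str]:
    """Return a list of invariant violations (empty if the trial is valid)."""
    p: list[str] = []
    if trial.decision not in DECISIONS:
        p.append(f"decision {trial.decision!r} not one of {DECISIONS}")
        return p
    if not 0 <= trial.zone_id <= 3:
        p.append(f"zone_id {trial.zone_id} outside 0-3")
    if trial.offered_delay <= 0:
        p.append(f"offered_delay {trial.offered_delay} not positive")
    if not -0.5 <= trial.entry_position <= 0.5:
        p.append(f"entry_position {trial.entry_position} outside [-0.5, 0.5]")
    if trial.t_exit < trial.t_offer:
        p.append(f"t_exit {trial.t_exit} < t_offer {trial.t_offer}")
    if trial.t_move is not None and not trial.t_offer <= trial.t_move <= trial.t_exit:
        p.append("t_move outside [t_offer, t_exit]")
    if version >= 3 and trial.t_move is None:
        # Versions 3-4 gate the avatar, so first movement should be logged;
        # treat absence as missing data, not an invariant violation.
        pass
    if trial.decision == "quit":
        if trial.t_delay_start is None or trial.t_quit_or_complete is None:
            p.append("quit without delay-start/quit timestamps")
        elif trial.waited_s >= trial.offered_delay:
            p.append("quit but waited time >= offered delay")
    if trial.decision == "stay":
        if trial.t_delay_start is None or trial.t_quit_or_complete is None:
            p.append("stay without delay-start/completion timestamps")
        elif trial.waited_s < trial.offered_delay - 1e-6:
            p.append("stay but waited time < offered delay")
    if trial.trajectory is not None and len(trial.trajectory):
        p.extend(trial.trajectory.problems())
        t = trial.trajectory.t
        if len(t) and (t[0] < trial.t_offer or t[-1] > trial.t_exit):
            p.append("trajectory timestamps outside [t_offer, t_exit]")
    return p


def validate_session(session: Session) -> list[str]:
    """Invariant violations for a whole session, prefixed by trial number."""
    p: list[str] = []
    if session.task_variant not in TASK_VARIANTS:
        p.append(f"task_variant {session.task_variant!r} unknown")
    if not 1 <= session.version <= 4:
        p.append(f"version {session.version} outside 1-4")
    if not session.trials:
        p.append("session has no trials")
    idx = [t.trial_index for t in session.trials]
    if idx != list(range(len(idx))):
        p.append("trial_index not contiguous from 0")
    if len({t.category for t in session.trials}) > 4:
        p.append("more than four reward categories")
    for trial in session.trials:
        for msg in validate_trial(trial, session.version):
            p.append(f"trial {trial.trial_index}: {msg}")
    for ev in session.magazine_events:
        if ev.duration <= 0:
            p.append(f"magazine event at {ev.t_start}: duration {ev.duration} <= 0")
    return p


def truncate_reentry(trial: TrialRecord) -> TrialRecord:
    """Drop trajectory samples after the first exit timestamp.

    The log writer already truncates at first exit; this is defense in depth
    for logs produced elsewhere.
    """
    traj = trial.trajectory
    if traj is None or not len(traj):
        return trial
    keep = traj.t <= trial.t_exit
    if keep.all():
        return trial
    trial.trajectory = Trajectory(traj.t[keep], traj.x[keep], traj.y[keep], traj.heading[keep])
    return trial


# ---------------------------------------------------------------------------
# Magazine retrieval scoring


def score_magazine_retrievals(
    events: Iterable[BeamBreak],
    window_end: int = MAGAZINE_WINDOW_MS,
    min_ms: int = RETRIEVAL_MIN_MS,
    max_ms: int = RETRIEVAL_MAX_MS,
) -> pd.DataFrame:
    """Score beam breaks as reward retrievals.

    Breaks lasting between ``min_ms`` and ``max_ms`` (inclusive on both ends)
    that start before ``window_end`` are retained. The default window is the
    first 20 minutes of the session; later breaks are discarded because
    uncollected rewards can occlude the sensor.

    Returns a DataFrame with columns ``zone_id``, ``t_start``, ``duration_ms``
    sorted by ``t_start``.
    """
    rows = []
    for ev in events:
        if ev.duration <= 0:
            raise ValidationError(f"beam break at t={ev.t_start} has non-positive duration")
        if min_ms <= ev.duration <= max_ms and ev.t_start < window_end:
            rows.append((ev.zone_id, ev.t_start, ev.duration))
    df = pd.DataFrame(rows, columns=["zone_id", "t_start", "duration_ms"])
    return df.sort_values("t_start", kind="stable").reset_index(drop=True)
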