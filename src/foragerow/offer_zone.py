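"""Per-trial offer-zone behavioral measures and VTE quantification.

The measures mirror the rodent vicarious trial-and-error (VTE) literature:
decision latency, reaction time (task versions 3-4 only), integrated path
distance, total rotation (the human analogue of IdPhi — the integrated
absolute angular change in heading over the offer-zone pass), rotation
reversals, cumulative pause time, and entry bias (lateral position on
entering the offer zone, -50% toward the reward to +50% toward the exit).

Exclusion rules: trials with decision latency above 15 s are removed from
all offer-zone measures; trials with more than 360 deg of total rotation
lose their rotation and reversal measures only. Reaction times above 15 s
are not analyzed.

All measures except reversal counts are strongly right-skewed, so they are
log10-transformed and z-scored within session before any cross-trial
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session, Trajectory, TrialRecord, ValidationError

__all__ = [
    "LATENCY_LIMIT_MS",
    "ROTATION_LIMIT_DEG",
    "REACTION_LIMIT_MS",
    "decision_latency",
    "reaction_time",
    "path_distance",
    "total_rotation",
    "rotation_reversals",
    "pause_time",
    "entry_bias_pct",
    "compute_session_metrics",
    "apply_exclusions",
    "normalize_within_session",
    "value_tuning",
    "cohort_slope_summary",
    "cohort_value_profile",
    "value_bin_edges",
]

logger = logging.getLogger("foragerow.offer_zone")

LATENCY_LIMIT_MS = 15_000
ROTATION_LIMIT_DEG = 360.0
REACTION_LIMIT_MS = 15_000

#: Measures that get the log10 + within-session z treatment. Reversal counts
#: are deliberately left untransformed.
NORMALIZED_MEASURES = ("latency_ms", "distance", "rotation_deg", "pause_ms", "reaction_ms")


def wrap_deg(delta):
    """Wrap heading differences to the minimal angle in (-180, 180]."""
    d = np.asarray(delta, float)
    out = (d + 180.0) % 360.0 - 180.0
    out = np.where(out == -180.0, 180.0, out)
    return out if out.ndim else float(out)


def decision_latency(trial: TrialRecord, version: int) -> float:
    """Time spent in the offer zone, ms.

    Versions 1-2 count from offer presentation; versions 3-4 (which gate the
    avatar) count from first movement. Returns NaN if the needed timestamp is
    missing.
    """
    if version >= 3:
        if trial.t_move is None:
            return float("nan")
        return float(trial.t_exit - trial.t_move)
    return float(trial.t_exit - trial.t_offer)


def reaction_time(trial: TrialRecord, version: int) -> float:
    """Offer presentation to first movement, ms (versions 3-4 only)."""
    if version < 3 or trial.t_move is None:
        return float("nan")
    return float(trial.t_move - trial.t_offer)


def path_distance(traj: Trajectory) -> float:
    """Integrated Euclidean distance over the trajectory, track units."""
    if len(traj) < 2:
        return float("nan")
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def total_rotation(traj: Trajectory) -> float:
    """Sum of absolute minimal-angle heading changes across samples, degrees.

    Heading differences are wrapped to (-180, 180] so crossing the 0/360 seam
    contributes the small angle (350 -> 10 counts 20 deg, not 340).
    """
    if len(traj) < 2:
        return float("nan")
    h = traj.heading
    if np.any(h < 0) or np.any(h >= 360):
        raise ValidationError("heading outside [0, 360)")
    return float(np.abs(wrap_deg(np.diff(h))).sum())


def rotation_reversals(traj: Trajectory, jitter_deg: float = 1.0) -> float:
    """Count sign changes of the heading increments.

    Increments smaller than ``jitter_deg`` in magnitude are discarded first so
    that sampling noise around a steady heading does not register as a stream
    of micro-reversals.
    """
    if len(traj) < 3:
        return float("nan")
    d = wrap_deg(np.diff(traj.heading))
    d = d[np.abs(d) >= jitter_deg]
    if len(d) < 2:
        return 0.0
    return float((np.sign(d[1:]) != np.sign(d[:-1])).sum())


def pause_time(traj: Trajectory, move_eps: float = 1e-6, heading_eps: float = 1.0) -> float:
    """Total time stopped (no position change and no rotation), ms.

    An inter-sample interval counts as paused when the displacement is below
    ``move_eps`` track units and the heading change is below ``heading_eps``
    degrees (an exact-equality reading with float tolerance on position).
    """
    if len(traj) < 2:
        return float("nan")
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    dh = np.abs(wrap_deg(np.diff(traj.heading)))
    paused = (disp < move_eps) & (dh < heading_eps)
    return float(np.diff(traj.t)[paused].sum())


def entry_bias_pct(entry_position: float) -> float:
    """Entry bias as percent of hallway width, -50 (reward side) to +50 (exit)."""
    if not -0.5 <= entry_position <= 0.5:
        raise ValidationError(f"entry position {entry_position} outside [-0.5, 0.5]")
    return 100.0 * entry_position


def _trajectory_metrics(traj: Optional[Trajectory], jitter_deg: float, move_eps: float):
    if traj is None or len(traj) < 2:
        return float("nan"), float("nan"), float("nan"), float("nan")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    disp = np.hypot(dx, dy)
    dh = wrap_deg(np.diff(traj.heading))
    adh = np.abs(dh)
    distance = float(disp.sum())
    rotation = float(adh.sum())
    sig = dh[adh >= jitter_deg]
    reversals = float((np.sign(sig[1:]) != np.sign(sig[:-1])).sum()) if len(sig) >= 2 else 0.0
    paused = (disp < move_eps) & (adh < 1.0)
    pause = float(np.diff(traj.t)[paused].sum())
    return distance, rotation, reversals, pause


def compute_session_metrics(
    session: Session,
    jitter_deg: float = 1.0,
    move_eps: float = 1e-6,
) -> pd.DataFrame:
    """Raw offer-zone measures for every trial of a session."""
    rows = []
    v = session.version
    for tr in session.trials:
        distance, rotation, reversals, pause = _trajectory_metrics(tr.trajectory, jitter_deg, move_eps)
        rows.append((
            tr.trial_index,
            decision_latency(tr, v),
            reaction_time(tr, v),
            distance, rotation, reversals, pause,
            entry_bias_pct(tr.entry_position),
        ))
    return pd.DataFrame(rows, columns=[
        "trial_index", "latency_ms", "reaction_ms", "distance",
        "rotation_deg", "n_reversals", "pause_ms", "entry_bias_pct",
    ])


def apply_exclusions(
    metrics: pd.DataFrame,
    latency_limit_ms: float = LATENCY_LIMIT_MS,
    rotation_limit_deg: float = ROTATION_LIMIT_DEG,
    reaction_limit_ms: float = REACTION_LIMIT_MS,
) -> tuple[pd.DataFrame, dict]:
    """Flag trials per the latency / rotation / reaction exclusion rules.

    A latency above the limit excludes the trial from *all* offer-zone
    measures; excessive rotation excludes the rotation and reversal measures
    only; an excessive reaction time excludes the reaction measure. Returns
    the flagged copy and a tally dict, which is also logged so that runs are
    auditable.
    """
    df = metrics.copy()
    df["excluded_latency"] = df["latency_ms"] > latency_limit_ms
    df["excluded_rotation"] = df["rotation_deg"] > rotation_limit_deg
    df["excluded_reaction"] = df["reaction_ms"] > reaction_limit_ms
    tallies = {
        "n_trials": int(len(df)),
        "excluded_latency": int(df["excluded_latency"].sum()),
        "excluded_rotation": int(df["excluded_rotation"].sum()),
        "excluded_reaction": int(df["excluded_reaction"].sum()),
    }
    logger.info(
        "exclusions: %d/%d trials over %.0f ms latency (all measures dropped); "
        "%d over %.0f deg rotation (rotation measures dropped); %d reaction times over %.0f ms",
        tallies["excluded_latency"], tallies["n_trials"], latency_limit_ms,
        tallies["excluded_rotation"], rotation_limit_deg,
        tallies["excluded_reaction"], reaction_limit_ms,
    )
    return df, tallies


def _log_z(values: np.ndarray, retained: np.ndarray, label: str) -> np.ndarray:
    """log10 then z-score over retained trials; NaN where not retained."""
    z = np.full(len(values), np.nan)
    v = values[retained]
    if len(v) < 2:
        return z
    v = v.astype(float).copy()
    pos = v[v > 0]
    if len(pos) == 0:
        z[retained] = 0.0
        warnings.warn(f"{label}: all values zero in session; z set to 0")
        return z
    offset = pos.min() / 2.0
    v[v <= 0] = offset
    lg = np.log10(v)
    sd = lg.std(ddof=0)
    if sd == 0:
        warnings.warn(f"{label}: zero variance in session; z set to 0")
        z[retained] = 0.0
    else:
        z[retained] = (lg - lg.mean()) / sd
    return z


def normalize_within_session(metrics: pd.DataFrame) -> pd.DataFrame:
    """Add within-session z-scores of the log10-transformed measures.

    Zeros (a trial with no pausing, say) are offset by half the smallest
    positive value of that measure in the session before the log. Reversal
    counts are carried through untransformed. Requires exclusion flags (see
    :func:`apply_exclusions`).
    """
    df = metrics.copy()
    keep = ~df["excluded_latency"].to_numpy(bool)
    keep_rot = keep & ~df["excluded_rotation"].to_numpy(bool)
    keep_rt = keep & ~df["excluded_reaction"].to_numpy(bool)
    retained = {
        "latency_ms": keep,
        "distance": keep,
        "pause_ms": keep,
        "rotation_deg": keep_rot,
        "reaction_ms": keep_rt,
    }
    short = {"latency_ms": "z_latency", "distance": "z_distance",
             "rotation_deg": "z_rotation", "pause_ms": "z_pause",
             "reaction_ms": "z_reaction"}
    for col, zcol in short.items():
        vals = df[col].to_numpy(float)
        ok = retained[col] & np.isfinite(vals)
        df[zcol] = _log_z(vals, ok, col)
    return df


# ---------------------------------------------------------------------------
# Value tuning


def value_bin_edges(bin_width: float = 2.0, lo: float = -27.0, hi: float = 27.0) -> np.ndarray:
    """Signed-value bin edges placed so one bin is centered on value 0."""
    half = bin_width / 2.0
    left = np.arange(-half, lo - bin_width, -bin_width)[::-1]
    right = np.arange(half, hi + bin_width, bin_width)
    return np.concatenate([left, right])


def value_tuning(
    z: np.ndarray,
    values: np.ndarray,
    bin_width: float = 2.0,
    min_trials: int = 10,
):
    """Per-participant value tuning of a normalized measure.

    Returns ``(bin_centers, binned_means, slope)`` where the slope is the
    ordinary least-squares slope of z on \\|value\\| — negative when the
    measure is elevated near value 0, the deliberation signature. Requires at
    least ``min_trials`` value-labeled trials.
    """
    z = np.asarray(z, float)
    values = np.asarray(values, float)
    ok = np.isfinite(z) & np.isfinite(values)
    z, values = z[ok], values[ok]
    if len(z) < min_trials:
        raise ValueError(f"need at least {min_trials} value-labeled trials, got {len(z)}")
    edges = value_bin_edges(bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    which = np.digitize(values, edges) - 1
    means = np.full(len(centers), np.nan)
    inside = (which >= 0) & (which < len(centers))
    for b in np.unique(which[inside]):
        means[b] = z[which == b].mean()
    absv = np.abs(values)
    if np.allclose(absv, absv[0]):
        slope = 0.0
    else:
        slope = float(np.polyfit(absv, z, 1)[0])
    return centers, means, slope


def cohort_slope_summary(slopes: Sequence[float], conf: float = 0.95):
    """Mean slope across participants with a t-based confidence interval."""
    s = np.asarray([x for x in slopes if np.isfinite(x)], float)
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 participants for a cohort summary")
    m = s.mean()
    se = s.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + conf / 2.0, n - 1)
    return m, (m - tcrit * se, m + tcrit * se), n


def cohort_value_profile(profiles: Sequence[np.ndarray], min_participants: int = 10):
    """Average per-participant binned profiles; bins with too few contributors
    are masked. Returns the mean profile (NaN where masked)."""
    arr = np.vstack(profiles)
    n = np.isfinite(arr).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
    mean[n < min_participants] = np.nan
    return mean
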