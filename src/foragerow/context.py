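"""Economic-context labels: regret conditions, choice sequences, overrides.

Regret-inducing trials are those where a participant receives a poor offer
(delay above threshold, value < 0) immediately after rejecting (skipping or
quitting) a good offer (value > 0) at the previous zone — they passed up a
better deal and now face a worse one. Two controls share the poor current
offer but differ in history: Control-1 follows *accepting* a good offer,
Control-2 follows rejecting an offer that was itself poor.

Sequential-choice cells cross the previous decision with the current one
(Skip/Skip, Skip/Stay, Stay/Skip, Stay/Stay); quits are grouped with skips
by default, matching the stay=1 / skip-or-quit=0 choice coding. The
"previous zone" is the immediately preceding trial in visit order (the
track is unidirectional).

An override is a choice against one's own threshold: accepting a poor offer
or rejecting a good one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "label_regret",
    "label_sequence",
    "label_override",
    "label_trials",
    "compare_contexts",
    "ContrastResult",
    "REGRET_CLASSES",
    "SEQUENCE_CELLS",
]

REGRET_CLASSES = ("regret", "control1", "control2", "none")
SEQUENCE_CELLS = ("skip_skip", "skip_stay", "stay_skip", "stay_stay", "undefined")


def _rejected(decision: str) -> bool:
    return decision in ("skip", "quit")


def label_regret(decisions: Sequence[str], values: Sequence[float]) -> list[str]:
    """Regret class per trial from decisions and offer values in visit order.

    A trial can only be regret/control when its own offer is poor
    (value < 0) and the previous trial has a usable (non-NaN, non-zero)
    value; everything else is ``none``.
    """
    values = np.asarray(values, float)
    out = ["none"] * len(values)
    for i in range(1, len(values)):
        cur, prev = values[i], values[i - 1]
        if not (np.isfinite(cur) and cur < 0):
            continue
        if not np.isfinite(prev) or prev == 0:
            continue
        prev_rejected = _rejected(decisions[i - 1])
        if prev > 0:
            out[i] = "regret" if prev_rejected else "control1"
        elif prev_rejected:
            out[i] = "control2"
    return out


def label_sequence(decisions: Sequence[str], quits: str = "skip") -> list[str]:
    """Sequence cell (previous decision x current decision) per trial.

    The first trial is ``undefined``. With ``quits="skip"`` (default) quits
    are grouped with skips on both sides of the pair; with
    ``quits="separate"`` any pair touching a quit is ``undefined``.
    """
    if quits not in ("skip", "separate"):
        raise ValueError("quits must be 'skip' or 'separate'")

    def norm(d: str) -> Optional[str]:
        if d == "quit":
            return "skip" if quits == "skip" else None
        return d

    out = ["undefined"]
    for i in range(1, len(decisions)):
        a, b = norm(decisions[i - 1]), norm(decisions[i])
        out.append(f"{a}_{b}" if a and b else "undefined")
    return out


def label_override(decisions: Sequence[str], values: Sequence[float]) -> list[bool]:
    """True where the choice went against the threshold: accepting a poor
    offer or rejecting a good one."""
    values = np.asarray(values, float)
    out = []
    for d, v in zip(decisions, values):
        if not np.isfinite(v) or v == 0:
            out.append(False)
        elif v < 0:
            out.append(d == "stay")
        else:
            out.append(_rejected(d))
    return out


def label_trials(trial_table: pd.DataFrame, quits: str = "skip") -> pd.DataFrame:
    """Attach regret, sequence and override labels to a per-trial table.

    ``trial_table`` must be in visit order with ``decision`` and ``value``
    columns (see :func:`foragerow.thresholds.fit_session_thresholds` plus the
    session decisions).
    """
    df = trial_table.sort_values("trial_index").reset_index(drop=True).copy()
    decisions = df["decision"].tolist()
    values = df["value"].to_numpy(float)
    df["regret_class"] = label_regret(decisions, values)
    df["sequence_cell"] = label_sequence(decisions, quits=quits)
    df["override"] = label_override(decisions, values)
    return df


@dataclass
class ContrastResult:
    cell_a: str
    cell_b: str
    mean_a: float
    mean_b: float
    per_participant: pd.DataFrame
    n_participants: int
    n_dropped: int
    wilcoxon_p: float


def compare_contexts(
    df: pd.DataFrame,
    metric: str,
    label_col: str,
    cell_a: str,
    cell_b: str,
    min_participants: int = 5,
) -> ContrastResult:
    """Paired within-participant contrast of a metric between two cells.

    Computes the participant-level mean of ``metric`` in each cell, drops
    participants missing either cell, and runs a Wilcoxon signed-rank test
    across the remaining pairs. ``df`` needs ``participant_id``, ``metric``
    and ``label_col`` columns. For the regret contrast on acceptance, pass a
    0/1 choice column as the metric.
    """
    sub = df[df[label_col].isin([cell_a, cell_b])]
    sub = sub[np.isfinite(sub[metric].to_numpy(float))]
    piv = sub.pivot_table(index="participant_id", columns=label_col, values=metric, aggfunc="mean")
    n_total = piv.shape[0]
    piv = piv.dropna(subset=[c for c in (cell_a, cell_b) if c in piv.columns]) \
        if {cell_a, cell_b}.issubset(piv.columns) else piv.iloc[0:0]
    n = piv.shape[0]
    if n < min_participants:
        raise ValueError(
            f"insufficient participants with both {cell_a!r} and {cell_b!r}: "
            f"{n} < {min_participants}")
    a = piv[cell_a].to_numpy(float)
    b = piv[cell_b].to_numpy(float)
    diffs = a - b
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    return ContrastResult(
        cell_a=cell_a, cell_b=cell_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        per_participant=piv.reset_index(),
        n_participants=n, n_dropped=n_total - n,
        wilcoxon_p=p,
    )
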