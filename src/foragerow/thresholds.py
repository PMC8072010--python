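"""Delay-threshold estimation by padded leave-one-out step-function fits.

For each reward category, stay/skip decisions (stay = 1, skip or quit = 0)
are fit as a step function of the offered delay: predict stay for every
delay strictly below a candidate threshold and skip at or above it, scoring
a candidate by the number of misclassified choices. Before fitting, the
choice set is padded with one synthetic stay 1 s below the minimum offered
delay and one synthetic skip 1 s above the maximum, so that all-accept and
all-reject patterns still yield a finite step location.

Thresholds are estimated leave-one-out: the threshold attached to trial i is
fit on every *other* offer of the same category (re-padded on that subset),
and the participant's overall threshold for the category is the arithmetic
mean of the per-trial thresholds. The threshold is the point at which the
participant is equally likely to stay or skip.

To catch participants who prefer *long* delays, the same procedure is run on
the inverted choices (1 - choice). A category is classified

* ``normal``          if the forward mean error is lower than the inverse,
* ``long_delay_pref`` if the inverse fits better,
* on a tie, ``full_stay`` if >= 75% of offers were accepted, ``full_skip``
  if <= 25% were, and ``unclassified`` otherwise.

Offer value is defined as threshold minus offered delay (positive = a
better-than-threshold offer; value 0 = maximally difficult).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChoicePoint",
    "ThresholdFit",
    "pad_choices",
    "fit_heaviside",
    "loo_thresholds",
    "classify_pattern",
    "offer_value",
    "fit_category",
    "fit_session_thresholds",
    "FULL_STAY_PROP",
    "FULL_SKIP_PROP",
]

#: Tie-break acceptance proportions for the degenerate response styles.
FULL_STAY_PROP = 0.75
FULL_SKIP_PROP = 0.25

PATTERNS = ("normal", "long_delay_pref", "full_stay", "full_skip", "unclassified")


@dataclass(frozen=True)
class ChoicePoint:
    """One stay/skip decision at a delay. ``padded`` marks synthetic points."""

    delay: float
    choice: int
    trial_index: int = -1
    padded: bool = False


@dataclass
class ThresholdFit:
    """Per participant x category threshold fit."""

    category: str
    overall_threshold: float
    loo_thresholds: np.ndarray
    forward_error: float
    inverse_error: float
    pattern: str
    prop_accepted: float
    trial_index: np.ndarray = field(default_factory=lambda: np.array([], int))


def pad_choices(points: Sequence[ChoicePoint]) -> list[ChoicePoint]:
    """Pad with one stay 1 s below the min delay and one skip 1 s above the max.

    The synthetic points carry ``padded=True`` and must never be treated as
    real trials downstream; passing already-padded input is rejected rather
    than padding twice.
    """
    points = list(points)
    if not points:
        raise ValueError("cannot pad an empty choice set")
    if any(p.padded for p in points):
        raise ValueError("input already contains padded points")
    delays = [p.delay for p in points]
    return points + [
        ChoicePoint(min(delays) - 1.0, 1, padded=True),
        ChoicePoint(max(delays) + 1.0, 0, padded=True),
    ]


def _fit_arrays(delays: np.ndarray, choices: np.ndarray) -> tuple[float, int]:
    order = np.argsort(delays, kind="stable")
    d = delays[order]
    c = choices[order]
    uniq = np.unique(d)
    if len(uniq) < 2:
        # Degenerate: a single delay value; the step location is unconstrained
        # between the padded bounds, use that delay itself.
        err = min(int((c == 1).sum()), int((c == 0).sum()))
        return float(uniq[0]), err
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    # For a candidate t: predicted stay iff delay < t.
    # error(t) = (#stays with delay >= t) + (#skips with delay < t)
    n_stay_total = int(c.sum())
    pos = np.searchsorted(d, candidates, side="left")  # points with delay < t
    cum_stay = np.concatenate([[0], np.cumsum(c)])
    stays_below = cum_stay[pos]
    skips_below = pos - stays_below
    errors = (n_stay_total - stays_below) + skips_below
    best = errors.min()
    thr = float(candidates[errors == best].mean())
    return thr, int(best)


def fit_heaviside(points: Sequence[ChoicePoint]) -> tuple[float, int]:
    """Fit a step function to padded choices, minimizing misclassifications.

    Candidate thresholds are the midpoints between consecutive sorted unique
    delays; among error-tied candidates the mean is returned. Returns
    ``(threshold_s, error_count)``.
    """
    if not any(p.padded for p in points):
        raise ValueError("fit_heaviside expects padded input (see pad_choices)")
    delays = np.array([p.delay for p in points], float)
    choices = np.array([p.choice for p in points], int)
    return _fit_arrays(delays, choices)


def _loo_fits(delays: np.ndarray, choices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out padded step fits; returns (thresholds, errors) per trial."""
    n = len(delays)
    thrs = np.empty(n)
    errs = np.empty(n, int)
    mask = np.ones(n, bool)
    for i in range(n):
        mask[i] = False
        d = delays[mask]
        c = choices[mask]
        dmin, dmax = d.min(), d.max()
        dd = np.concatenate([d, [dmin - 1.0, dmax + 1.0]])
        cc = np.concatenate([c, [1, 0]])
        thrs[i], errs[i] = _fit_arrays(dd, cc)
        mask[i] = True
    return thrs, errs


def loo_thresholds(points: Sequence[ChoicePoint]) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial leave-one-out thresholds and fit errors for real choice points.

    The i-th threshold is fit on every other real point, re-padded on that
    subset. Requires at least 2 real points.
    """
    real = [p for p in points if not p.padded]
    if len(real) < 2:
        raise ValueError("leave-one-out needs at least 2 real choice points")
    delays = np.array([p.delay for p in real], float)
    choices = np.array([p.choice for p in real], int)
    return _loo_fits(delays, choices)


def classify_pattern(forward_error: float, inverse_error: float, prop_accepted: float) -> str:
    """Classify the response pattern from forward/inverse mean errors.

    Normal if the forward step fits strictly better, long-delay preference if
    the inverse fits strictly better; on a tie the 75% acceptance rule picks
    full-stay or full-skip, and everything else is unclassified.
    """
    if forward_error < inverse_error:
        return "normal"
    if forward_error > inverse_error:
        return "long_delay_pref"
    if prop_accepted >= FULL_STAY_PROP:
        return "full_stay"
    if prop_accepted <= FULL_SKIP_PROP:
        return "full_skip"
    return "unclassified"


def offer_value(offered_delay: float, loo_threshold: float, pattern: str = "normal"):
    """Offer value = threshold - offered delay, with its type.

    Positive values are good offers (delay below threshold), negative are
    poor, and exactly-at-threshold offers are ``boundary``. For categories
    without a usable threshold (pattern not ``normal``) the value is
    unavailable (NaN).
    """
    if pattern != "normal" or not np.isfinite(loo_threshold):
        return float("nan"), "unavailable", float("nan")
    value = loo_threshold - offered_delay
    if value > 0:
        vtype = "good"
    elif value < 0:
        vtype = "poor"
    else:
        vtype = "boundary"
    return value, vtype, abs(value)


def fit_category(points: Sequence[ChoicePoint], category: str = "") -> ThresholdFit:
    """Full threshold fit for one reward category.

    Runs the leave-one-out padded step fits on the choices and on the
    inverted choices, averages errors and thresholds across trials, and
    classifies the response pattern. With fewer than 2 real points the
    category is forced to ``unclassified``.
    """
    real = [p for p in points if not p.padded]
    prop = float(np.mean([p.choice for p in real])) if real else float("nan")
    if len(real) < 2:
        return ThresholdFit(category, float("nan"), np.full(len(real), np.nan),
                            float("nan"), float("nan"), "unclassified", prop,
                            np.array([p.trial_index for p in real], int))
    delays = np.array([p.delay for p in real], float)
    choices = np.array([p.choice for p in real], int)
    thrs, errs = _loo_fits(delays, choices)
    _, inv_errs = _loo_fits(delays, 1 - choices)
    fwd = float(errs.mean())
    inv = float(inv_errs.mean())
    pattern = classify_pattern(fwd, inv, prop)
    return ThresholdFit(
        category=category,
        overall_threshold=float(thrs.mean()),
        loo_thresholds=thrs,
        forward_error=fwd,
        inverse_error=inv,
        pattern=pattern,
        prop_accepted=prop,
        trial_index=np.array([p.trial_index for p in real], int),
    )


def fit_session_thresholds(session) -> tuple[dict, pd.DataFrame]:
    """Fit thresholds for every category of a session.

    Returns ``(fits, trial_table)`` where ``fits`` maps category ->
    :class:`ThresholdFit` and ``trial_table`` has one row per trial with the
    leave-one-out threshold, offer value, value type and |value|.
    """
    by_cat: dict[str, list[ChoicePoint]] = {}
    for tr in session.trials:
        by_cat.setdefault(tr.category, []).append(
            ChoicePoint(tr.offered_delay, tr.choice, tr.trial_index))

    fits = {cat: fit_category(pts, cat) for cat, pts in by_cat.items()}

    rows = []
    for cat, fit in fits.items():
        for i, idx in enumerate(fit.trial_index):
            pt = by_cat[cat][i]
            loo = fit.loo_thresholds[i] if len(fit.loo_thresholds) else float("nan")
            value, vtype, absv = offer_value(pt.delay, loo, fit.pattern)
            rows.append((idx, cat, pt.delay, pt.choice, loo, value, vtype, absv))
        if len(fit.trial_index) == 0:
            for pt in by_cat[cat]:
                rows.append((pt.trial_index, cat, pt.delay, pt.choice,
                             float("nan"), float("nan"), "unavailable", float("nan")))
    table = pd.DataFrame(
        rows, columns=["trial_index", "category", "offered_delay", "choice",
                       "loo_threshold", "value", "value_type", "abs_value"],
    ).sort_values("trial_index").reset_index(drop=True)
    return fits, table
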