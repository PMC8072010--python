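"""Hyperbolic delay-discounting scoring for binary choice questionnaires.

Each item offers a smaller immediate reward against a larger delayed one;
under hyperbolic discounting V = A / (1 + k * D) an item is an indifference
probe at its *implied k* = (delayed/immediate - 1) / delay. A responder with
discount rate k should choose the delayed option exactly when the item's
implied k exceeds k. Scoring therefore scans candidate k values — the
geometric midpoints between consecutive sorted implied ks, plus one
geometric step beyond each extreme — and picks the candidate(s) most
consistent with the observed responses (consistency scoring in the style
standard for the 27-item monetary questionnaire); ties are resolved by the
geometric mean of the maximizing candidates. Per-magnitude-bin rates are
scored the same way within bins, and contrasts of log10 k across bins
quantify the magnitude effect.

Two item banks ship with the package as editable CSVs: a 21-item monetary
bank and a 27-item food bank (amounts in bites of one's favorite food).
Both are synthetic reconstructions built to span the canonical implied-k
range in geometric steps across three magnitude bins; the exact published
amounts live in their original sources and any bank with the documented
columns can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurveyItem",
    "DiscountingResult",
    "load_item_bank",
    "implied_k",
    "score_survey",
    "magnitude_effect",
]

ITEM_COLUMNS = ("immediate_amount", "delayed_amount", "delay_days", "magnitude_bin")
BUNDLED_BANKS = {"mcq21": "mcq21_items_synthetic.csv", "fcq27": "fcq27_items_synthetic.csv"}


@dataclass(frozen=True)
class SurveyItem:
    immediate_amount: float
    delayed_amount: float
    delay_days: float
    magnitude_bin: str

    @property
    def implied_k(self) -> float:
        return (self.delayed_amount / self.immediate_amount - 1.0) / self.delay_days


@dataclass
class DiscountingResult:
    k_overall: float
    log10_k: float
    consistency: float
    k_per_bin: dict
    n_items_scored: int


def load_item_bank(name_or_path) -> pd.DataFrame:
    """Load an item bank: a bundled name ("mcq21", "fcq27") or a CSV path."""
    if str(name_or_path) in BUNDLED_BANKS:
        ref = resources.files("foragerow.data") / BUNDLED_BANKS[str(name_or_path)]
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(name_or_path, comment="#")
    missing = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"item bank missing columns {missing}")
    bad = (df["delayed_amount"] <= df["immediate_amount"]) | (df["immediate_amount"] <= 0) \
        | (df["delay_days"] <= 0)
    if bad.any():
        raise ValueError(f"invalid item rows: {list(df.index[bad])}")
    return df


def implied_k(items: pd.DataFrame) -> np.ndarray:
    return ((items["delayed_amount"] / items["immediate_amount"] - 1.0)
            / items["delay_days"]).to_numpy(float)


def _candidates(ks: np.ndarray) -> np.ndarray:
    """Geometric midpoints of sorted unique implied ks plus outer bounds."""
    u = np.unique(ks)
    if len(u) == 1:
        return np.array([u[0] / 2.0, u[0] * 2.0])
    mids = np.sqrt(u[:-1] * u[1:])
    lo = u[0] / np.sqrt(u[1] / u[0])
    hi = u[-1] * np.sqrt(u[-1] / u[-2])
    return np.concatenate([[lo], mids, [hi]])


def _best_k(ks: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    """Consistency-maximizing k (geometric mean over ties) and consistency."""
    cand = _candidates(ks)
    # predicted delayed choice iff implied k > candidate; items at exact
    # equality are indifference probes, consistent with either response
    pred = ks[None, :] > cand[:, None]
    agree = (pred == resp[None, :].astype(bool)) | np.isclose(ks[None, :], cand[:, None])
    cons = agree.mean(axis=1)
    best = cons.max()
    winners = cand[cons == best]
    k = float(np.exp(np.mean(np.log(winners))))
    return k, float(best)


def score_survey(
    responses: Sequence[float],
    items: pd.DataFrame,
    max_missing: float = 0.3,
) -> DiscountingResult:
    """Score a binary response vector (1 = delayed, 0 = immediate) against an
    item bank.

    Missing responses (NaN) drop the item with a warning; if more than
    ``max_missing`` of the items are missing, scoring is refused. Scoring is
    invariant to item order.
    """
    resp = np.asarray(responses, float)
    if len(resp) != len(items):
        raise ValueError(f"got {len(resp)} responses for {len(items)} items")
    ok = np.isfinite(resp)
    if (~ok).sum() > max_missing * len(resp):
        raise ValueError(
            f"{(~ok).sum()}/{len(resp)} responses missing exceeds {max_missing:.0%}")
    if (~ok).any():
        warnings.warn(f"dropping {(~ok).sum()} item(s) with missing responses")
    ks = implied_k(items)[ok]
    r = resp[ok].astype(int)
    if not np.isin(r, (0, 1)).all():
        raise ValueError("responses must be 0/1 (or NaN for missing)")

    k_overall, cons = _best_k(ks, r)
    k_per_bin = {}
    bins = items["magnitude_bin"].to_numpy()[ok]
    for b in pd.unique(bins):
        sel = bins == b
        if sel.sum() >= 2:
            k_per_bin[b], _ = _best_k(ks[sel], r[sel])
    return DiscountingResult(
        k_overall=k_overall,
        log10_k=float(np.log10(k_overall)),
        consistency=cons,
        k_per_bin=k_per_bin,
        n_items_scored=int(ok.sum()),
    )


def magnitude_effect(result: DiscountingResult) -> dict:
    """Pairwise differences of per-bin log10 k (e.g. small - large > 0 when
    larger rewards are discounted less)."""
    bins = list(result.k_per_bin)
    if len(bins) < 2:
        raise ValueError("magnitude effect needs at least 2 scored bins")
    out = {}
    for i, a in enumerate(bins):
        for b in bins[i + 1:]:
            out[f"{a}-{b}"] = float(np.log10(result.k_per_bin[a]) - np.log10(result.k_per_bin[b]))
    return out
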