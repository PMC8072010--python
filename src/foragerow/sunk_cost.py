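"""Sunk-cost sensitivity: conditional completion curves and entry-bias model.

Two complementary measures of sensitivity to irrecoverable investments:

1. **Conditional completion curves.** Among trials where the delay countdown
   was started and at least T seconds were waited (the investment), the
   probability of completing the remainder of the delay is tabulated against
   the time remaining (delay - T). A memoryless quitter gives the same
   negative slope at every investment; a sunk-cost-sensitive quitter's slope
   flattens (|slope| shrinks) as the investment grows, because time already
   waited suppresses quitting. Slope uncertainty comes from a seeded
   participant-level bootstrap (percentile intervals).

2. **Entry-bias choice model.** The lateral position at which a participant
   enters the offer zone is an effort investment made before the offer is
   revealed; entering toward the exit makes skipping cheaper. A logistic
   model of stay/skip on deviation-coded value type (-0.5 good / +0.5 poor),
   continuous entry bias (fraction of hallway width, -0.5..+0.5), optional
   gender, their two-way interactions and per-participant intercepts
   quantifies the effect. Fitting is penalized maximum likelihood (weak
   ridge on the participant intercepts only, which also clamps intercepts
   for participants with one-sided choices); inference is Wald.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CompletionCurve",
    "EntryBiasModel",
    "completion_trials",
    "completion_curves",
    "compare_investment_slopes",
    "fit_entry_bias_model",
    "bias_effect_summary",
]

logger = logging.getLogger("foragerow.sunk_cost")


# ---------------------------------------------------------------------------
# Completion curves


@dataclass
class CompletionCurve:
    invested: float
    table: pd.DataFrame  # columns: remaining, n_trials, n_complete, p_complete
    slope: float
    slope_ci: tuple
    n_participants: int


def completion_trials(sessions) -> pd.DataFrame:
    """Extract delay-started trials: participant, delay, waited, completed."""
    rows = []
    for s in sessions:
        for tr in s.trials:
            if tr.t_delay_start is None or tr.waited_s is None:
                continue
            rows.append((s.participant_id, tr.offered_delay, tr.waited_s,
                         1 if tr.decision == "stay" else 0))
    return pd.DataFrame(rows, columns=["participant_id", "delay", "waited", "completed"])


def _counts_matrix(df: pd.DataFrame, invested: float, max_remaining: Optional[float] = None):
    """Per-participant completion counts by integer remaining time.

    Returns (participants, remaining_values, n[p, r], k[p, r]) where n is the
    trial count and k the completions. ``max_remaining`` drops longer
    remainders, which puts curves at different investments on a common
    support when comparing their slopes.
    """
    sel = df[(df["waited"] >= invested) & (df["delay"] > invested)]
    if max_remaining is not None:
        sel = sel[sel["delay"] - invested <= max_remaining]
    if sel.empty:
        return [], np.array([], int), np.zeros((0, 0)), np.zeros((0, 0))
    remaining = np.rint(sel["delay"].to_numpy(float) - invested).astype(int)
    pids = sel["participant_id"].to_numpy()
    completed = sel["completed"].to_numpy(int)
    upids, pidx = np.unique(pids, return_inverse=True)
    urem, ridx = np.unique(remaining, return_inverse=True)
    n = np.zeros((len(upids), len(urem)))
    k = np.zeros((len(upids), len(urem)))
    np.add.at(n, (pidx, ridx), 1)
    np.add.at(k, (pidx, ridx), completed)
    return list(upids), urem, n, k


def _wls_slope(remaining: np.ndarray, n: np.ndarray, k: np.ndarray):
    """Weighted LS slope of p_complete on remaining, weights = trial counts.

    ``n``/``k`` may be 1-D (one curve) or 2-D (bootstrap replicates x bins).
    """
    n = np.atleast_2d(n)
    k = np.atleast_2d(k)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    w = n.astype(float)
    sw = w.sum(axis=1)
    x = remaining.astype(float)
    xbar = (w * x).sum(axis=1) / sw
    pbar = np.nansum(w * p, axis=1) / sw
    dx = x[None, :] - xbar[:, None]
    dp = np.where(n > 0, p - pbar[:, None], 0.0)
    varx = (w * dx**2).sum(axis=1)
    cov = (w * dx * dp).sum(axis=1)
    slope = np.where(varx > 0, cov / np.where(varx > 0, varx, 1.0), 0.0)
    return slope if slope.size > 1 else float(slope[0])


def completion_curves(
    trials: pd.DataFrame,
    investments: Sequence[float] = (0.0, 5.0, 10.0),
    n_bootstrap: int = 2000,
    seed=0,
    per_participant_average: bool = False,
    max_remaining: Optional[float] = None,
) -> dict:
    """Completion-probability curves conditioned on time invested.

    For each investment T, restricts to trials with waited >= T and delay > T,
    bins by integer remaining time, and fits a trial-count-weighted LS slope
    of completion probability on remaining time, with a percentile CI from
    ``n_bootstrap`` participant-level resamples. ``per_participant_average``
    switches the point estimate from pooled counts to the mean of
    per-participant completion proportions. When slopes at different
    investments are to be compared, pass ``max_remaining`` so every curve is
    fit over the same remaining-time support; otherwise the longer support of
    small investments dilutes their slope and the comparison confounds
    hazard change with range change.

    Returns {investment: CompletionCurve}.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for T in investments:
        pids, urem, n, k = _counts_matrix(trials, T, max_remaining)
        if len(pids) == 0:
            logger.info("investment %.0fs: no qualifying trials", T)
            out[T] = CompletionCurve(T, pd.DataFrame(
                columns=["remaining", "n_trials", "n_complete", "p_complete"]),
                float("nan"), (float("nan"), float("nan")), 0)
            continue
        ntot = n.sum(axis=0)
        ktot = k.sum(axis=0)
        if per_participant_average:
            with np.errstate(invalid="ignore", divide="ignore"):
                pp = np.where(n > 0, k / np.maximum(n, 1), np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pcol = np.nanmean(pp, axis=0)
        else:
            pcol = np.where(ntot > 0, ktot / np.maximum(ntot, 1), np.nan)
        table = pd.DataFrame({
            "remaining": urem, "n_trials": ntot.astype(int),
            "n_complete": ktot.astype(int), "p_complete": pcol,
        })
        slope = _wls_slope(urem, ntot, ktot)
        if n_bootstrap > 0 and len(pids) > 1:
            idx = rng.integers(0, len(pids), size=(n_bootstrap, len(pids)))
            counts = np.zeros((n_bootstrap, len(pids)))
            for b in range(n_bootstrap):
                np.add.at(counts[b], idx[b], 1)
            bs_n = counts @ n
            bs_k = counts @ k
            bs = _wls_slope(urem, bs_n, bs_k)
            ci = (float(np.percentile(bs, 2.5)), float(np.percentile(bs, 97.5)))
        else:
            ci = (float("nan"), float("nan"))
        out[T] = CompletionCurve(T, table, slope, ci, len(pids))
    return out


def compare_investment_slopes(
    trials: pd.DataFrame,
    invest_a: float,
    invest_b: float,
    n_bootstrap: int = 2000,
    seed=0,
    max_remaining: Optional[float] = None,
    conf: float = 0.95,
):
    """Bootstrap the slope difference between two investment levels.

    Uses common participant resamples for both levels, and by preference a
    common remaining-time support (``max_remaining``). Returns
    ``(diff, (lo, hi))`` — the point difference slope(a) - slope(b) and its
    percentile interval at level ``conf``; a difference smaller than the
    interval half-width is the memoryless (no sunk-cost) signature. For
    that equivalence-style reading a conservative level (``conf=0.99``) is
    recommended: quits are rare events, and participant resampling slightly
    underestimates the spread of rare-event statistics.
    """
    pids_a, rem_a, n_a, k_a = _counts_matrix(trials, invest_a, max_remaining)
    pids_b, rem_b, n_b, k_b = _counts_matrix(trials, invest_b, max_remaining)
    if not pids_a or not pids_b:
        raise ValueError("no qualifying trials at one of the investment levels")
    all_pids = sorted(set(pids_a) | set(pids_b))
    P = len(all_pids)
    pos = {p: j for j, p in enumerate(all_pids)}

    def expand(pids, n, k):
        N = np.zeros((P, n.shape[1]))
        K = np.zeros((P, k.shape[1]))
        for row, p in enumerate(pids):
            N[pos[p]] = n[row]
            K[pos[p]] = k[row]
        return N, K

    Na, Ka = expand(pids_a, n_a, k_a)
    Nb, Kb = expand(pids_b, n_b, k_b)
    diff = _wls_slope(rem_a, Na.sum(0), Ka.sum(0)) - _wls_slope(rem_b, Nb.sum(0), Kb.sum(0))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, P, size=(n_bootstrap, P))
    counts = np.zeros((n_bootstrap, P))
    for b in range(n_bootstrap):
        np.add.at(counts[b], idx[b], 1)
    bs = _wls_slope(rem_a, counts @ Na, counts @ Ka) - _wls_slope(rem_b, counts @ Nb, counts @ Kb)
    alpha = 100 * (1 - conf) / 2
    ci = (float(np.percentile(bs, alpha)), float(np.percentile(bs, 100 - alpha)))
    return float(diff), ci


# ---------------------------------------------------------------------------
# Entry-bias choice model


@dataclass
class EntryBiasModel:
    params: pd.Series       # named coefficients (slopes)
    se: pd.Series
    intercepts: pd.Series   # per-participant
    cov: np.ndarray         # covariance of the slope block
    slope_names: list
    loglik: float
    n_obs: int
    converged: bool
    n_clusters: int = 0
    robust: bool = True

    def ci(self, name: str, conf: float = 0.95):
        from scipy import stats as _st
        if self.robust and self.n_clusters > 1:
            # cluster-robust inference: t reference with G-1 df
            crit = _st.t.ppf(0.5 + conf / 2.0, self.n_clusters - 1)
        else:
            crit = _st.norm.ppf(0.5 + conf / 2.0)
        return (self.params[name] - crit * self.se[name],
                self.params[name] + crit * self.se[name])

    def predict_p_stay(self, value_type_dev: float, entry_bias: float,
                       gender_dev: float = 0.0) -> float:
        """Predicted acceptance probability at the mean participant intercept."""
        eta = float(self.intercepts.mean())
        x = {"value_type": value_type_dev, "entry_bias": entry_bias,
             "gender": gender_dev,
             "value_type:entry_bias": value_type_dev * entry_bias,
             "value_type:gender": value_type_dev * gender_dev,
             "entry_bias:gender": entry_bias * gender_dev}
        for name in self.slope_names:
            eta += self.params[name] * x[name]
        return float(expit(eta))


def _penalized_logistic(X, y, penalty, max_iter=200, tol=1e-9, start=None):
    """Newton/IRLS for ridge-penalized logistic regression.

    ``penalty`` is the diagonal of the ridge matrix (0 for unpenalized
    columns). Returns (beta, cov, loglik, converged); the log-likelihood is
    monitored and steps are halved if it would decrease.
    """
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, float).copy()
    Lam = np.diag(penalty)

    def pen_ll(b):
        eta = X @ b
        return float(y @ eta - np.logaddexp(0, eta).sum() - 0.5 * b @ (penalty * b))

    ll = pen_ll(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - penalty * beta
        H = (X.T * W) @ X + Lam
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            new_ll = pen_ll(beta + t * step)
            if new_ll >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        if abs(new_ll - ll) < tol and np.max(np.abs(t * step)) < 1e-6:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    eta = X @ beta
    mu = expit(eta)
    W = np.clip(mu * (1 - mu), 1e-10, None)
    H = (X.T * W) @ X + Lam
    cov = np.linalg.inv(H)
    return beta, cov, ll, converged


def fit_entry_bias_model(
    df: pd.DataFrame,
    include_gender: bool = False,
    ridge: float = 0.5,
    se_method: str = "jackknife",
) -> EntryBiasModel:
    """Fit the stay/skip ~ value type x entry bias model.

    ``df`` needs columns ``participant_id``, ``choice`` (1 stay / 0 skip or
    quit), ``value_type`` ("good"/"poor"; boundary and unavailable trials are
    dropped), ``entry_bias`` (fraction of hallway width in [-0.5, 0.5]) and,
    if ``include_gender``, ``gender``. Value type is deviation coded
    -0.5 = good / +0.5 = poor; gender -0.5 = male / +0.5 = female.

    ``ridge`` is the weak penalty applied to participant intercepts only; it
    keeps intercepts finite for participants whose choices are one-sided
    (complete separation) and is negligible otherwise.

    ``se_method`` controls the slope standard errors: ``"jackknife"``
    (default) deletes one participant at a time and refits — the
    best-calibrated choice when the binary value-type term only approximates
    each participant's latent valuation; ``"sandwich"`` is the
    participant-clustered CR1 sandwich (faster, slightly anti-conservative);
    ``"naive"`` is the model-based Wald covariance. Confidence intervals use
    a t reference with (participants - 1) degrees of freedom for the two
    cluster-based methods.
    """
    sub = df[df["value_type"].isin(["good", "poor"])].copy()
    pids = sub["participant_id"].unique()
    if len(pids) < 2:
        raise ValueError("entry-bias model needs at least 2 participants")
    if sub["value_type"].nunique() < 2:
        raise ValueError("both value types must be present")

    one_sided = [p for p, g in sub.groupby("participant_id")["choice"] if g.nunique() < 2]
    if one_sided:
        warnings.warn(
            f"{len(one_sided)} participant(s) with one-sided choices; "
            "intercepts clamped by the ridge penalty")

    vt = np.where(sub["value_type"] == "poor", 0.5, -0.5)
    eb = sub["entry_bias"].to_numpy(float)
    y = sub["choice"].to_numpy(float)
    pidx = pd.Categorical(sub["participant_id"], categories=pids).codes
    P = len(pids)
    Xint = np.zeros((len(sub), P))
    Xint[np.arange(len(sub)), pidx] = 1.0

    cols = [vt, eb, vt * eb]
    names = ["value_type", "entry_bias", "value_type:entry_bias"]
    if include_gender:
        gd = np.where(sub["gender"].astype(str).str.lower().str.startswith("f"), 0.5, -0.5)
        cols += [gd, vt * gd, eb * gd]
        names += ["gender", "value_type:gender", "entry_bias:gender"]
    Xslope = np.column_stack(cols)
    X = np.hstack([Xint, Xslope])
    penalty = np.concatenate([np.full(P, ridge), np.zeros(Xslope.shape[1])])

    if se_method not in ("jackknife", "sandwich", "naive"):
        raise ValueError(f"unknown se_method {se_method!r}")
    beta, cov, ll, converged = _penalized_logistic(X, y, penalty)
    nslope = Xslope.shape[1]
    if se_method == "sandwich":
        # participant-clustered sandwich with the CR1 small-sample scaling:
        # cov = c * H^-1 (sum_c g_c g_c^T) H^-1, c = G/(G-1)
        mu = expit(X @ beta)
        resid = y - mu
        G = np.zeros((P, X.shape[1]))
        np.add.at(G, pidx, X * resid[:, None])
        W = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X.T * W) @ X + np.diag(penalty)
        Hinv = np.linalg.inv(H)
        cov = (P / (P - 1)) * Hinv @ (G.T @ G) @ Hinv
        slope_cov = cov[P:, P:]
    elif se_method == "jackknife":
        # delete-one-participant jackknife over the slope block
        jk = np.empty((P, nslope))
        for g in range(P):
            keep = pidx != g
            cols = np.ones(X.shape[1], bool)
            cols[g] = False
            bg, _, _, _ = _penalized_logistic(X[np.ix_(keep, cols)], y[keep],
                                              penalty[cols], start=beta[cols])
            jk[g] = bg[P - 1:]
        m = jk.mean(axis=0)
        slope_cov = (P - 1) / P * (jk - m).T @ (jk - m)
    else:
        slope_cov = cov[P:, P:]
    se_slopes = np.sqrt(np.diag(slope_cov))
    return EntryBiasModel(
        params=pd.Series(beta[P:], index=names),
        se=pd.Series(se_slopes, index=names),
        intercepts=pd.Series(beta[:P], index=pids),
        cov=slope_cov,
        slope_names=names,
        loglik=ll,
        n_obs=len(sub),
        converged=converged,
        n_clusters=P,
        robust=se_method != "naive",
    )


def bias_effect_summary(model: EntryBiasModel, bias_point: float = 0.25) -> dict:
    """Model-predicted acceptance changes at shifted entry positions.

    Mirrors the sunk-cost reading of entry bias: how much more often are poor
    offers accepted when entering 25% toward the reward side (bias -0.25)
    versus center, and how much more often are good offers skipped when
    entering 25% toward the exit (+0.25) versus center. Values are
    percentage-point changes.
    """
    if not 0 <= bias_point <= 0.5:
        raise ValueError("bias_point must be within [0, 0.5] of hallway width")
    p_poor_center = model.predict_p_stay(0.5, 0.0)
    p_poor_left = model.predict_p_stay(0.5, -bias_point)
    p_good_center = model.predict_p_stay(-0.5, 0.0)
    p_good_right = model.predict_p_stay(-0.5, bias_point)
    return {
        "poor_accepted_change_pct": 100.0 * (p_poor_left - p_poor_center),
        "good_skipped_change_pct": 100.0 * ((1 - p_good_right) - (1 - p_good_center)),
    }
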