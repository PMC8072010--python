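"""Completion curves, slope bootstrap, and the entry-bias choice model."""

import numpy as np
import pandas as pd
import pytest

from foragerow import sunk_cost as sc
from foragerow.simulate import AgentConfig, TaskConfig, generate_cohort
from foragerow.sunk_cost import _counts_matrix, _penalized_logistic


def _trials_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "delay", "waited", "completed"])


class TestCompletionCurves:
    def test_no_quits_gives_flat_unit_curve(self):
        rows = [("p1", d, d, 1) for d in range(3, 30)] * 3 + \
               [("p2", d, d, 1) for d in range(3, 30)] * 3
        curves = sc.completion_curves(_trials_frame(rows), (0.0, 5.0), n_bootstrap=50)
        for c in curves.values():
            assert (c.table["p_complete"] == 1.0).all()
            assert c.slope == pytest.approx(0.0, abs=1e-12)

    def test_counts_conserved_across_investments(self):
        """Trials entering investment T equal completions plus quits after T."""
        coh = generate_cohort(
            5, seed=0,
            base_agent=AgentConfig(response_style=("full_stay",) * 4,
                                   quit_hazard_base=0.05, sunk_cost_strength=0.0),
            task=TaskConfig(include_trajectories=False))
        trials = sc.completion_trials(coh)
        for T in (0, 5, 10):
            _, _, n, k = _counts_matrix(trials, T)
            sel = trials[(trials.waited >= T) & (trials.delay > T)]
            quits_after = ((sel.completed == 0)).sum()
            assert n.sum() == len(sel)
            assert k.sum() == len(sel) - quits_after

    def test_empty_investment_level_logged_not_fatal(self):
        rows = [("p1", 5.0, 5.0, 1)]
        curves = sc.completion_curves(_trials_frame(rows), (20.0,), n_bootstrap=0)
        assert curves[20.0].table.empty and np.isnan(curves[20.0].slope)

    def test_per_participant_average_variant(self):
        rows = [("p1", 10.0, 10.0, 1), ("p1", 10.0, 2.0, 0),
                ("p2", 10.0, 10.0, 1), ("p2", 10.0, 10.0, 1)]
        pooled = sc.completion_curves(_trials_frame(rows), (0.0,), n_bootstrap=0)
        avg = sc.completion_curves(_trials_frame(rows), (0.0,), n_bootstrap=0,
                                   per_participant_average=True)
        assert pooled[0.0].table["p_complete"].iloc[0] == pytest.approx(3 / 4)
        assert avg[0.0].table["p_complete"].iloc[0] == pytest.approx((0.5 + 1.0) / 2)

    def test_memoryless_slopes_equal_common_support(self):
        """Constant hazard: slope does not depend on investment (analytic
        geometric-survival oracle says the conditional curves coincide)."""
        ag = AgentConfig(response_style=("full_stay",) * 4,
                         quit_hazard_base=0.01, sunk_cost_strength=0.0)
        coh = generate_cohort(60, seed=12, base_agent=ag,
                              task=TaskConfig(include_trajectories=False))
        trials = sc.completion_trials(coh)
        d, ci = sc.compare_investment_slopes(trials, 0, 10, n_bootstrap=600,
                                             seed=0, max_remaining=19)
        assert ci[0] <= d <= ci[1]
        assert abs(d) < (ci[1] - ci[0]) / 2


class TestPenalizedLogistic:
    def test_matches_statsmodels_on_clean_data(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 800
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta_true = np.array([0.3, -1.0, 0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        beta, cov, ll, conv = _penalized_logistic(X, y, np.zeros(3))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert conv
        assert np.allclose(beta, ref.params, atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-4)

    def test_loglik_nondecreasing_to_convergence(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        lls = []
        beta = np.zeros(2)
        for it in range(1, 12):
            b, _, ll, _ = _penalized_logistic(X, y, np.zeros(2), max_iter=it)
            lls.append(ll)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def _vt_frame(cohort, use_true_theta=True):
    from foragerow.simulate import CATEGORIES
    rows = []
    for s in cohort:
        ag = s.covariates["_true_agent"]
        th = dict(zip(CATEGORIES, ag.thresholds))
        for t in s.trials:
            v = th[t.category] - t.offered_delay
            rows.append((s.participant_id, t.choice, v, t.entry_position,
                         s.covariates.get("gender", "male")))
    df = pd.DataFrame(rows, columns=["participant_id", "choice", "value", "entry_bias", "gender"])
    df["value_type"] = np.where(df["value"] > 0, "good",
                                np.where(df["value"] < 0, "poor", "boundary"))
    return df


class TestEntryBiasModel:
    def test_recovers_sign_of_planted_bias(self):
        coh = generate_cohort(
            30, seed=21,
            base_agent=AgentConfig(bias_choice_coef=2.0, deliberation_gain=0.0),
            task=TaskConfig(include_trajectories=False))
        m = sc.fit_entry_bias_model(_vt_frame(coh), se_method="sandwich")
        assert m.params["entry_bias"] < 0
        assert m.params["value_type"] < 0  # poor offers accepted less

    def test_single_participant_rejected(self):
        coh = generate_cohort(1, seed=1, task=TaskConfig(include_trajectories=False))
        with pytest.raises(ValueError, match="participants"):
            sc.fit_entry_bias_model(_vt_frame(coh))

    def test_one_sided_participant_warns_but_fits(self):
        coh = generate_cohort(
            4, seed=2,
            base_agent=AgentConfig(response_style=("full_stay",) * 4, quit_hazard_base=0.0),
            task=TaskConfig(include_trajectories=False))
        noisy = generate_cohort(4, seed=3, task=TaskConfig(include_trajectories=False))
        a = _vt_frame(coh)
        a["participant_id"] = "stay_" + a["participant_id"]
        df = pd.concat([a, _vt_frame(noisy)]).reset_index(drop=True)
        with pytest.warns(UserWarning, match="one-sided"):
            m = sc.fit_entry_bias_model(df, se_method="naive")
        assert np.isfinite(m.intercepts).all()

    def test_gender_terms_included_on_request(self):
        coh = generate_cohort(10, seed=4, task=TaskConfig(include_trajectories=False))
        m = sc.fit_entry_bias_model(_vt_frame(coh), include_gender=True, se_method="naive")
        assert "entry_bias:gender" in m.params.index


class TestBiasEffectSummary:
    def test_zero_coefficient_zero_change(self):
        coh = generate_cohort(
            20, seed=5,
            base_agent=AgentConfig(bias_choice_coef=0.0, deliberation_gain=0.0),
            task=TaskConfig(include_trajectories=False))
        m = sc.fit_entry_bias_model(_vt_frame(coh), se_method="naive")
        m.params["entry_bias"] = 0.0
        m.params["value_type:entry_bias"] = 0.0
        eff = sc.bias_effect_summary(m)
        assert eff["poor_accepted_change_pct"] == pytest.approx(0.0, abs=1e-9)
        assert eff["good_skipped_change_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_logistic_difference(self):
        from scipy.special import expit
        coh = generate_cohort(
            20, seed=6,
            base_agent=AgentConfig(bias_choice_coef=2.0, deliberation_gain=0.0),
            task=TaskConfig(include_trajectories=False))
        m = sc.fit_entry_bias_model(_vt_frame(coh), se_method="naive")
        b0 = m.intercepts.mean()
        bvt, beb, bint = (m.params["value_type"], m.params["entry_bias"],
                          m.params["value_type:entry_bias"])
        expected = expit(b0 + 0.5 * bvt + (-0.25) * (beb + 0.5 * bint)) - \
            expit(b0 + 0.5 * bvt)
        eff = sc.bias_effect_summary(m, bias_point=0.25)
        assert eff["poor_accepted_change_pct"] == pytest.approx(100 * expected, abs=1e-6)

    def test_bias_point_outside_hallway_rejected(self):
        coh = generate_cohort(5, seed=7, task=TaskConfig(include_trajectories=False))
        m = sc.fit_entry_bias_model(_vt_frame(coh), se_method="naive")
        with pytest.raises(ValueError):
            sc.bias_effect_summary(m, bias_point=0.75)


def test_refit_on_model_simulated_data_recovers_coefficients(rng):
    """Full-cycle check: simulate choices from a fitted model's own equation,
    refit, and recover the planted coefficients."""
    n_p, n_t = 40, 100
    truth = {"value_type": -2.0, "entry_bias": -1.5, "value_type:entry_bias": 0.0}
    rows = []
    for p in range(n_p):
        icept = rng.normal(0.5, 0.5)
        vt = rng.choice([-0.5, 0.5], size=n_t)
        eb = np.clip(rng.normal(0, 0.15, size=n_t), -0.5, 0.5)
        eta = icept + truth["value_type"] * vt + truth["entry_bias"] * eb
        y = (rng.random(n_t) < 1 / (1 + np.exp(-eta))).astype(int)
        for i in range(n_t):
            rows.append((f"p{p}", y[i], "poor" if vt[i] > 0 else "good", eb[i]))
    df = pd.DataFrame(rows, columns=["participant_id", "choice", "value_type", "entry_bias"])
    m = sc.fit_entry_bias_model(df, se_method="sandwich")
    for name, tv in truth.items():
        lo = m.params[name] - 3 * m.se[name]
        hi = m.params[name] + 3 * m.se[name]
        assert lo <= tv <= hi
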