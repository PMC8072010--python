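"""Offer-zone VTE measures, exclusion rules and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foragerow.session import Trajectory, TrialRecord, ValidationError
from foragerow import offer_zone as oz


def traj(headings, dt=50, xy=None):
    n = len(headings)
    t = np.arange(n) * dt
    if xy is None:
        x = np.arange(n) * 0.01
        y = np.zeros(n)
    else:
        x, y = xy
    return Trajectory(t.astype(float), np.asarray(x, float), np.asarray(y, float),
                      np.asarray(headings, float))


def make_trial(**kw):
    base = dict(trial_index=0, zone_id=0, category="a", offered_delay=10.0,
                decision="skip", t_offer=0, t_exit=2000)
    base.update(kw)
    return TrialRecord(**base)


class TestLatencyAndReaction:
    def test_latency_from_move_in_v4(self):
        tr = make_trial(t_move=1000, t_exit=3700)
        assert oz.decision_latency(tr, 4) == 2700

    def test_latency_from_offer_in_v2(self):
        tr = make_trial(t_offer=0, t_exit=2000)
        assert oz.decision_latency(tr, 2) == 2000

    def test_latency_missing_move_unavailable(self):
        assert np.isnan(oz.decision_latency(make_trial(), 4))

    def test_reaction_time_and_version_gate(self):
        tr = make_trial(t_move=800)
        assert oz.reaction_time(tr, 4) == 800
        assert np.isnan(oz.reaction_time(tr, 2))

    def test_reaction_exclusion_is_strictly_greater(self):
        m, _ = oz.apply_exclusions(_metrics_with_reaction([15_000, 15_001]))
        assert m["excluded_reaction"].tolist() == [False, True]


def _metrics_with_reaction(reactions):
    import pandas as pd
    return pd.DataFrame({
        "trial_index": range(len(reactions)),
        "latency_ms": [2000.0] * len(reactions),
        "reaction_ms": [float(r) for r in reactions],
        "distance": 1.0, "rotation_deg": 10.0, "n_reversals": 0.0,
        "pause_ms": 0.0, "entry_bias_pct": 0.0,
    })


class TestPathDistance:
    def test_stationary_zero(self):
        assert oz.path_distance(traj([0, 0, 0], xy=(np.zeros(3), np.zeros(3)))) == 0

    def test_three_four_five(self):
        tr = Trajectory(np.array([0., 50.]), np.array([0., 3.]), np.array([0., 4.]),
                        np.array([0., 0.]))
        assert oz.path_distance(tr) == pytest.approx(5.0)

    def test_matches_pairwise_oracle_on_random_walks(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 60))
            x, y = rng.normal(size=(2, n))
            tr = Trajectory(np.arange(n) * 50.0, x, y, np.zeros(n))
            oracle = sum(np.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) for i in range(n - 1))
            assert oz.path_distance(tr) == pytest.approx(oracle, abs=1e-9)


class TestRotation:
    def test_constant_heading_zero(self):
        assert oz.total_rotation(traj([45] * 10)) == 0

    def test_out_and_back(self):
        assert oz.total_rotation(traj([0, 90, 0])) == 180

    def test_wrap_at_seam(self):
        assert oz.total_rotation(traj([350, 10])) == pytest.approx(20)

    def test_heading_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            oz.total_rotation(traj([0, 370]))

    @given(st.lists(st.floats(0, 359.99), min_size=2, max_size=30),
           st.floats(0, 359.99))
    @settings(max_examples=60, deadline=None)
    def test_rotation_invariant_to_heading_offset_and_mirror(self, headings, offset):
        base = oz.total_rotation(traj(headings))
        shifted = oz.total_rotation(traj([(h + offset) % 360 for h in headings]))
        mirrored = oz.total_rotation(traj([(360 - h) % 360 for h in headings]))
        # exclude knife-edge 180-degree increments, where wrap direction flips
        incs = np.abs(oz.wrap_deg(np.diff(np.asarray(headings))))
        if np.any(np.abs(incs - 180) < 1e-6):
            return
        assert shifted == pytest.approx(base, abs=1e-6)
        assert mirrored == pytest.approx(base, abs=1e-6)


class TestReversals:
    def test_monotone_sweep_zero(self):
        assert oz.rotation_reversals(traj([0, 10, 20, 30, 40])) == 0

    def test_zigzag_counts_sign_changes(self):
        assert oz.rotation_reversals(traj([0, 90, 45, 90])) == 2

    def test_jitter_threshold_filters_noise(self):
        h = [0, 0.5, 0, 0.5, 0, 90]  # sub-degree wiggles then a real turn
        assert oz.rotation_reversals(traj(h), jitter_deg=1.0) == 0


class TestPause:
    def test_identical_samples_sum_intervals(self):
        tr = traj([90] * 10, xy=(np.zeros(10), np.zeros(10)))
        # 9 intervals of 50 ms with no motion
        assert oz.pause_time(tr) == 450

    def test_continuous_motion_zero(self):
        assert oz.pause_time(traj([0] * 10)) == 0

    def test_pause_plus_motion_covers_window(self):
        n = 20
        x = np.concatenate([np.arange(10) * 0.01, np.full(10, 0.09)])
        tr = Trajectory(np.arange(n) * 50.0, x, np.zeros(n), np.zeros(n))
        window = tr.t[-1] - tr.t[0]
        moving = ((np.hypot(np.diff(tr.x), np.diff(tr.y)) >= 1e-6)
                  * np.diff(tr.t)).sum()
        assert oz.pause_time(tr) + moving == pytest.approx(window)


class TestEntryBias:
    @pytest.mark.parametrize("pos,pct", [(0.0, 0.0), (-0.5, -50.0), (0.25, 25.0)])
    def test_scaling(self, pos, pct):
        assert oz.entry_bias_pct(pos) == pct

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            oz.entry_bias_pct(0.6)


class TestExclusions:
    def test_latency_rule_drops_everything_rotation_rule_only_rotation(self):
        import pandas as pd
        df = pd.DataFrame({
            "trial_index": [0, 1, 2],
            "latency_ms": [16_000.0, 5_000.0, 14_900.0],
            "reaction_ms": [np.nan] * 3,
            "distance": 1.0, "rotation_deg": [100.0, 400.0, 350.0],
            "n_reversals": 0.0, "pause_ms": 0.0, "entry_bias_pct": 0.0,
        })
        out, tallies = oz.apply_exclusions(df)
        assert out["excluded_latency"].tolist() == [True, False, False]
        assert out["excluded_rotation"].tolist() == [False, True, False]
        assert tallies["excluded_latency"] == 1 and tallies["excluded_rotation"] == 1


class TestNormalization:
    def test_z_scores_have_mean_zero_sd_one(self, default_session):
        m = oz.compute_session_metrics(default_session)
        m, _ = oz.apply_exclusions(m)
        m = oz.normalize_within_session(m)
        keep = ~m["excluded_latency"]
        z = m.loc[keep, "z_latency"]
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1, abs=1e-9)

    def test_reversals_left_untransformed(self, default_session):
        m = oz.compute_session_metrics(default_session)
        m, _ = oz.apply_exclusions(m)
        out = oz.normalize_within_session(m)
        assert "z_n_reversals" not in out.columns
        assert (out["n_reversals"] == m["n_reversals"]).all()

    def test_degenerate_constant_values_warn_and_zero(self):
        import pandas as pd
        df = pd.DataFrame({
            "trial_index": range(5), "latency_ms": 2000.0, "reaction_ms": np.nan,
            "distance": 1.0, "rotation_deg": 5.0, "n_reversals": 0.0,
            "pause_ms": 0.0, "entry_bias_pct": 0.0,
        })
        df, _ = oz.apply_exclusions(df)
        with pytest.warns(UserWarning):
            out = oz.normalize_within_session(df)
        assert (out["z_latency"] == 0).all()


class TestValueTuning:
    def test_constant_z_gives_zero_slope(self):
        z = np.ones(30)
        v = np.linspace(-10, 10, 30)
        _, _, slope = oz.value_tuning(z, v)
        assert slope == pytest.approx(0, abs=1e-12)

    def test_requires_minimum_trials(self):
        with pytest.raises(ValueError):
            oz.value_tuning(np.ones(5), np.arange(5))

    def test_zero_bin_centered(self):
        edges = oz.value_bin_edges(2.0)
        which = np.digitize([0.0], edges)[0] - 1
        lo, hi = edges[which], edges[which + 1]
        assert lo < 0 < hi and hi - lo == 2.0
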