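"""Primary single-trial metrics: anchors, oracles, invariants."""

import numpy as np
import pytest

from helpers import naive_cohens_d_profile, path_slice

from vefkit.config import Geometry, MetricParams
from vefkit.errors import UndefinedMetricError
from vefkit.metrics import (
    compute_metric_table,
    hit_index,
    lick_position,
    local_path_reliability,
    path_reliability,
    path_surplus,
    reaction_time,
    running_speed,
    target_distance,
)
from vefkit.session_io import ContinuousTrace, SessionData, segment_trials
from vefkit.synthetic import direction_change_slice

GEOM = Geometry()
PARAMS = MetricParams()


class TestHitIndexAndTargetDistance:
    def test_logged_outcome_is_authoritative(self):
        s = path_slice(0.0, side="left", outcome="target")
        assert hit_index(s, GEOM) == 1
        assert target_distance(s, GEOM) == 0.0

    def test_neither_touch_between_targets(self):
        s = path_slice(lambda y: 0.0, side="left")  # ends at x=0, between walls
        assert s.outcome == "neither"
        assert hit_index(s, GEOM) == 0

    def test_distractor_touch(self):
        s = path_slice(lambda y: 12.0 * y / 48.0, side="left")  # ends at +12
        assert hit_index(s, GEOM) == -1

    def test_one_position_miss_anchors_to_one(self):
        # target left (near edge -7.5), animal at +4.5, spacing 12 -> TD = 1
        s = path_slice(lambda y: 4.5 * y / 48.0, side="left")
        assert target_distance(s, GEOM) == pytest.approx(1.0)

    def test_straight_through_centre(self):
        s = path_slice(0.0, side="left")
        assert target_distance(s, GEOM) == pytest.approx(7.5 / 12.0)

    def test_opposite_far_edge_is_two(self):
        s = path_slice(lambda y: 16.5 * y / 48.0, side="left")
        assert target_distance(s, GEOM) == pytest.approx(2.0)

    def test_excluded_trials_are_undefined(self):
        s = path_slice(0.0, side="centre", include=False)
        with pytest.raises(UndefinedMetricError):
            hit_index(s, GEOM)


class TestPathReliability:
    def test_hand_computed_profile_value(self):
        # XL = -10 +- e, XR = +10 +- e with per-side SD exactly 2, n = 10
        e = np.sqrt(6.0)
        offsets = [e, e, e, -e, -e, -e, 0.0, 0.0, 0.0, 0.0]
        trials = [path_slice(-10.0 + o, side="left", trial_id=i) for i, o in enumerate(offsets)]
        trials += [path_slice(10.0 + o, side="right", trial_id=10 + i) for i, o in enumerate(offsets)]
        res = path_reliability(trials, GEOM, PARAMS)
        assert res.pr_score == pytest.approx(10.0, abs=1e-9)
        assert res.n_left == res.n_right == 10

    def test_identical_side_distributions_give_zero(self):
        trials = [path_slice(float(v), side="left", trial_id=i)
                  for i, v in enumerate([-2, 0, 2, 4])]
        trials += [path_slice(float(v), side="right", trial_id=4 + i)
                   for i, v in enumerate([-2, 0, 2, 4])]
        res = path_reliability(trials, GEOM, PARAMS)
        assert res.pr_score == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_oracle_on_random_instances(self, rng):
        step = PARAMS.pr_grid_step
        y_grid = np.arange(GEOM.trigger_y, GEOM.target_y + 1e-9, step)
        for _ in range(50):
            n_l = int(rng.integers(2, 8))
            n_r = int(rng.integers(2, 8))
            trials = []
            paths_l, paths_r = [], []
            for i in range(n_l + n_r):
                n = int(rng.integers(40, 90))
                y = np.sort(rng.uniform(0, 48, n))
                x = np.cumsum(rng.normal(0, 1.0, n))
                side = "left" if i < n_l else "right"
                t = np.arange(n) / 60.0
                s = path_slice(0.0, side=side, trial_id=i)
                s.y, s.x = y, x
                s.time = t
                trials.append(s)
                (paths_l if side == "left" else paths_r).append((y, x))
            res = path_reliability(trials, GEOM, PARAMS)
            oracle = naive_cohens_d_profile(paths_l, paths_r, y_grid, step)
            expected = [v for v in oracle if v is not None and np.isfinite(v)]
            if not expected:
                assert res is None or np.isnan(res.pr_score)
                continue
            assert res.pr_score == pytest.approx(max(expected), abs=1e-10)

    def test_undefined_below_two_per_side(self):
        trials = [path_slice(-10.0, side="left", trial_id=0),
                  path_slice(10.0, side="right", trial_id=1),
                  path_slice(11.0, side="right", trial_id=2)]
        assert path_reliability(trials, GEOM, PARAMS) is None

    def test_local_pr_defined_count(self, rng):
        trials = [
            path_slice(float(-10 + rng.normal(0, 1)) if i % 2 == 0 else float(10 + rng.normal(0, 1)),
                       side="left" if i % 2 == 0 else "right", trial_id=i)
            for i in range(30)
        ]
        local = local_path_reliability(trials, GEOM, PARAMS)
        assert np.isnan(local[:7]).all() and np.isnan(local[-7:]).all()
        assert np.isfinite(local[7:-7]).all()
        assert np.isfinite(local).sum() == 16

    def test_correcting_an_error_never_lowers_pr(self, rng):
        base = []
        for i in range(16):
            side = "left" if i % 2 == 0 else "right"
            x = (-10 if side == "left" else 10) + rng.normal(0, 1.5)
            base.append(path_slice(float(x), side=side, trial_id=i))
        # introduce one error: a left trial running to the right side
        err = path_slice(10.0, side="left", trial_id=99)
        with_error = base + [err]
        fixed = base + [path_slice(-10.0, side="left", trial_id=99)]
        pr_err = path_reliability(with_error, GEOM, PARAMS).pr_score
        pr_fix = path_reliability(fixed, GEOM, PARAMS).pr_score
        assert pr_fix >= pr_err


class TestReactionTime:
    @pytest.mark.parametrize("rt_true", [0.2, 0.5, 1.0])
    @pytest.mark.parametrize("law", ["linear", "exponential"])
    def test_noiseless_onset_recovery(self, rt_true, law):
        s = direction_change_slice(rt_true, law=law)
        est, reason = reaction_time(s, PARAMS)
        assert reason == "ok"
        assert abs(est - rt_true) <= 2.0 / 60.0 + 1e-9

    def test_constant_path_is_undefined(self):
        s = path_slice(0.0, side="left")
        est, reason = reaction_time(s, PARAMS)
        assert np.isnan(est) and reason == "no_direction_change"

    def test_subcriterion_slope_deviation_is_undefined(self):
        # steady drift throughout: slope stays ~1 everywhere
        s = path_slice(lambda y: 0.05 * y, side="left")
        est, reason = reaction_time(s, PARAMS)
        assert np.isnan(est)

    def test_rt_respects_bounds(self, demo_table):
        rts = demo_table["reaction_time"].dropna()
        lo, hi = PARAMS.rt_bounds
        assert ((rts >= lo - 1e-9) & (rts <= hi + 1e-9)).all()


class TestPathSurplus:
    def test_straight_line_path_is_zero(self):
        s = direction_change_slice(0.3, law="linear", drift_rate=4.0)
        # straight segments: actual path ~ ideal chord within discretisation
        ps = path_surplus_for(s)
        assert abs(ps) < 0.15

    def test_detour_lengthens_path_by_known_factor(self):
        # construct: decision at (0, 24); path goes to (12, 24) then (12, 48)
        # actual = 12 + 24 = 36; ideal = hypot(12, 24) = 26.83 -> PS = 0.3416
        fs = 60.0
        seg1 = np.linspace(0, 24, 100)          # run forward to y=24 at x=0
        seg2 = np.linspace(0, 12, 50)           # sidestep at constant y
        seg3 = np.linspace(24, 48, 100)         # forward to target at x=12
        x = np.concatenate([np.zeros(100), seg2, np.full(100, 12.0)])
        y = np.concatenate([seg1, np.full(50, 24.0), seg3])
        n = len(x)
        t = np.arange(n) / fs
        s = path_slice(0.0, side="right")
        s.x, s.y, s.time = x, y, t
        s.shift_time = 0.0
        rt = t[99]  # decision at the end of the first segment
        ps = path_surplus(s, rt, GEOM)
        assert ps == pytest.approx(36.0 / np.hypot(12.0, 24.0) - 1.0, abs=1e-6)

    def test_undefined_rt_gives_undefined_ps(self):
        s = path_slice(0.0, side="left")
        assert np.isnan(path_surplus(s, float("nan"), GEOM))


def path_surplus_for(s):
    est, _ = reaction_time(s, PARAMS)
    return path_surplus(s, est, GEOM)


class TestLickPositionAndSpeed:
    def test_licks_at_target_row_give_zero(self):
        s = path_slice(0.0, side="left")
        licks = np.zeros(s.n_samples, dtype=int)
        licks[-1] = 1  # the sample at the target row
        s.lick = licks
        assert lick_position(s, None, GEOM, PARAMS) == pytest.approx(0.0, abs=0.2)

    def test_mean_of_two_anticipatory_licks(self):
        s = path_slice(0.0, side="left")
        licks = np.zeros(s.n_samples, dtype=int)
        i20 = int(np.argmin(np.abs(s.y - 28.0)))  # 20 cm before target
        i10 = int(np.argmin(np.abs(s.y - 38.0)))  # 10 cm before target
        licks[i20] = licks[i10] = 1
        s.lick = licks
        assert lick_position(s, None, GEOM, PARAMS) == pytest.approx(-15.0, abs=0.2)

    def test_no_licks_is_undefined(self):
        s = path_slice(0.0, side="left")
        assert np.isnan(lick_position(s, None, GEOM, PARAMS))

    def test_next_trial_licks_count_as_positive(self):
        s = path_slice(0.0, side="left")
        nxt = path_slice(0.0, side="centre", include=False)
        licks = np.zeros(nxt.n_samples, dtype=int)
        i25 = int(np.argmin(np.abs(nxt.y - 25.0)))
        licks[i25] = 1
        nxt.lick = licks
        assert lick_position(s, nxt, GEOM, PARAMS) == pytest.approx(25.0, abs=0.2)

    def test_constant_speed_recovered_exactly(self):
        fs = 60.0
        speed = 20.0
        s = path_slice(-12.0, side="left", speed=speed, fs=fs)
        val, reached = running_speed(s, GEOM, PARAMS)
        assert reached
        assert val == pytest.approx(speed, rel=1e-6)

    def test_two_plateau_speed_is_sample_weighted_mean(self):
        fs = 60.0
        # forward at 10 cm/s for 2 s then 20 cm/s until the target
        y1 = np.arange(0, 20, 10 / fs)
        y2 = np.arange(20, 48 + 1e-9, 20 / fs)
        y = np.concatenate([y1, y2])
        x = np.full(len(y), -12.0)
        s = path_slice(0.0, side="left")
        s.x, s.y = x, y
        s.time = np.arange(len(y)) / fs
        s.shift_time = s.time[len(y1)]  # shift exactly at the speed change
        s.lick = np.zeros(len(y), dtype=int)
        val, reached = running_speed(s, GEOM, PARAMS)
        # span: from shift (y=20) to within 10 cm of target centre
        assert reached
        assert val == pytest.approx(20.0, rel=1e-3)


class TestMetricTable:
    def test_row_count_and_propagated_nans(self, demo_session, demo_table):
        _, session, _ = demo_session
        assert len(demo_table) == len(session.events)
        excluded = demo_table[~demo_table["include_flag"]]
        assert excluded["hit_index"].isna().all()

    def test_hit_td_consistency(self, demo_table):
        inc = demo_table[demo_table["include_flag"]]
        hits = inc["hit_index"] == 1
        assert (inc.loc[hits, "target_distance"] == 0).all()
        assert (inc.loc[~hits, "target_distance"] > 0).all()

    def test_lick_permutation_leaves_trajectory_metrics(self, demo_session, rng):
        _, session, _ = demo_session
        base = compute_metric_table(session)
        tbl = session.trace.table.copy()
        tbl["lick"] = rng.permutation(tbl["lick"].to_numpy())
        shuffled = SessionData(
            session.events,
            ContinuousTrace(tbl, session.trace.sample_rate),
            session.metadata,
        )
        perm = compute_metric_table(shuffled)
        for col in ("reaction_time", "target_distance", "path_surplus",
                    "hit_index", "local_pr", "running_speed"):
            a, b = base[col].to_numpy(float), perm[col].to_numpy(float)
            assert np.allclose(a, b, equal_nan=True)

    def test_delta_ori_permutation_leaves_all_metrics(self, demo_session, rng):
        _, session, _ = demo_session
        base = compute_metric_table(session)
        ev = session.events.table.copy()
        choice = ev["side"] != "centre"
        ev.loc[choice, "delta_ori"] = rng.permutation(ev.loc[choice, "delta_ori"].to_numpy())
        shuffled = SessionData(type(session.events)(ev), session.trace, session.metadata)
        perm = compute_metric_table(shuffled)
        for col in ("reaction_time", "target_distance", "path_surplus",
                    "hit_index", "local_pr", "running_speed", "lick_position"):
            a, b = base[col].to_numpy(float), perm[col].to_numpy(float)
            assert np.allclose(a, b, equal_nan=True)

    def test_metrics_invariant_under_reserialization(self, tmp_path, demo_session, demo_table):
        from vefkit.session_io import read_session, write_session

        _, session, _ = demo_session
        write_session(session, tmp_path)
        again = compute_metric_table(read_session(tmp_path))
        for col in ("hit_index", "target_distance", "reaction_time",
                    "path_surplus", "lick_position", "running_speed", "local_pr"):
            assert np.allclose(
                demo_table[col].to_numpy(float), again[col].to_numpy(float),
                equal_nan=True, atol=1e-6,
            )
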