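"""Bimodality, cut points, alertness-state labels, sATT, controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from helpers import naive_bimodality, naive_cut, path_slice

from vefkit.config import Geometry, Kinematics, MetricParams, SimConfig, StateTruth
from vefkit.errors import NotBimodalError, ValidationError
from vefkit.metrics import compute_metric_table, local_path_reliability
from vefkit.session_io import segment_trials
from vefkit.states import (
    bimodality_coefficient,
    classify_states,
    error_reassignment_control,
    find_cut_point,
    mixture_bc_crossing,
    mixture_bc_large_n,
    smoothed_metric_correlations,
)
from vefkit.synthetic import generate_session
from vefkit import benchmarks

GEOM = Geometry()
PARAMS = MetricParams()


class TestBimodalityCoefficient:
    def test_matches_naive_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), int(rng.integers(5, 60)))
            assert bimodality_coefficient(x).bc == pytest.approx(
                naive_bimodality(list(x)), abs=1e-12
            )

    def test_matches_scipy_moments(self, rng):
        x = rng.gamma(2.0, 1.5, 500)
        res = bimodality_coefficient(x)
        assert res.skew == pytest.approx(sps.skew(x, bias=True), abs=1e-12)
        assert res.kurt == pytest.approx(sps.kurtosis(x, fisher=False, bias=True), abs=1e-12)

    def test_large_normal_sample_approaches_one_third(self, rng):
        x = rng.standard_normal(100_000)
        assert bimodality_coefficient(x).bc == pytest.approx(1.0 / 3.0, abs=0.02)

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            bimodality_coefficient(np.array([1.0, 2.0, 3.0]))

    def test_mixture_crossing_near_3_6_sd(self):
        d = mixture_bc_crossing()
        assert d == pytest.approx(3.6, abs=0.1)
        assert mixture_bc_large_n(d - 0.2) < 0.55 < mixture_bc_large_n(d + 0.2)


class TestCutPoint:
    def test_two_well_separated_groups(self):
        res = find_cut_point(np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0]))
        assert 0.0 < res.cut < 10.0
        assert res.f_max == np.inf or res.f_max > 1.0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 120))
            x = np.concatenate([
                rng.normal(0, 1, n // 2), rng.normal(rng.uniform(2, 8), 1, n - n // 2)
            ])
            mine = find_cut_point(x)
            cut, fmax = naive_cut(list(x))
            assert mine.cut == pytest.approx(cut, abs=1e-12)

    def test_two_gaussian_clusters_cut_in_gap(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(0, 1, 500), r.normal(8, 1, 500)])
            c = find_cut_point(x).cut
            hits += 2.0 <= c <= 6.0
        assert hits >= 19

    def test_unimodal_f_much_smaller_than_bimodal(self, rng):
        uni = find_cut_point(rng.normal(0, 1, 400)).f_max
        bi = find_cut_point(np.concatenate([rng.normal(0, 1, 200),
                                            rng.normal(8, 1, 200)])).f_max
        assert bi > 5 * uni

    def test_constant_samples_rejected(self):
        with pytest.raises(ValidationError):
            find_cut_point(np.full(10, 2.0))


class TestClassifyStates:
    def make_bimodal(self, rng, n=200, high_frac=0.4):
        n_hi = int(n * high_frac)
        lp = np.concatenate([rng.normal(1.0, 0.3, n - n_hi), rng.normal(6.0, 0.8, n_hi)])
        rng.shuffle(lp)
        return lp

    def test_labels_consistent_with_cut(self, rng):
        lp = self.make_bimodal(rng)
        dur = np.full(len(lp), 8.0)
        cls = classify_states(lp, dur)
        assert ((lp > cls.cut) == (cls.labels == "high")).all()
        assert 0.0 <= cls.satt <= 1.0
        assert cls.satt == pytest.approx(cls.high_time / cls.total_time)

    def test_satt_uses_durations_not_counts(self, rng):
        lp = self.make_bimodal(rng)
        dur = np.full(len(lp), 8.0)
        base = classify_states(lp, dur).satt
        dur2 = dur.copy()
        dur2[lp > 4.0] *= 2.0  # lengthen the high trials
        assert classify_states(lp, dur2).satt > base

    def test_undefined_local_pr_contributes_no_time(self, rng):
        lp = self.make_bimodal(rng)
        dur = np.full(len(lp), 8.0)
        lp2 = lp.copy()
        lp2[:10] = np.nan
        cls = classify_states(lp2, dur)
        assert cls.total_time == pytest.approx((len(lp) - 10) * 8.0)
        assert all(lab is None for lab in cls.labels[:10])

    def test_unimodal_distribution_raises(self, rng):
        lp = rng.normal(3.0, 0.5, 300)
        with pytest.raises(NotBimodalError):
            classify_states(lp, np.full(300, 8.0))

    def test_episode_durations_sum_to_state_time(self, rng):
        lp = self.make_bimodal(rng)
        dur = np.full(len(lp), 8.0)
        cls = classify_states(lp, dur)
        ep = cls.episodes
        assert ep.loc[ep["state"] == "high", "duration"].sum() == pytest.approx(cls.high_time)


class TestErrorReassignment:
    def test_error_free_session_is_noop(self, rng):
        trials = []
        for i in range(60):
            side = "left" if i % 2 == 0 else "right"
            x = (-10 if side == "left" else 10) + rng.normal(0, 1.2)
            trials.append(path_slice(float(x), side=side, outcome="target", trial_id=i))
        control = error_reassignment_control(trials, GEOM, PARAMS, seed=0)
        base = bimodality_coefficient(
            local_path_reliability(trials, GEOM, PARAMS)[7:-7]
        )
        assert control.bc == pytest.approx(base.bc, abs=1e-12)

    def test_isolated_errors_fake_bimodality_collapses(self, rng):
        # tight correct paths with one opposite-side error every 12 trials:
        # local PR dips around each error create apparent bimodality that
        # must vanish once errors are reassigned to hit paths
        trials = []
        for i in range(150):
            side = "left" if i % 2 == 0 else "right"
            if i % 12 == 5:
                x = (10 if side == "left" else -10) + rng.normal(0, 1.0)
                outcome = "distractor"
            else:
                x = (-10 if side == "left" else 10) + rng.normal(0, 1.0)
                outcome = "target"
            trials.append(path_slice(float(x), side=side, outcome=outcome, trial_id=i))
        local = local_path_reliability(trials, GEOM, PARAMS)
        original = bimodality_coefficient(local[~np.isnan(local)])
        control = error_reassignment_control(trials, GEOM, PARAMS, seed=1)
        assert control.bc < original.bc
        assert control.bc < 0.55

    def test_state_driven_bimodality_survives(self):
        cfg = benchmarks.satt_config(0.5, n_trials=400, seed=6)
        # genuine path-quality contrast: the low state keeps loose paths
        # even on correct trials
        from dataclasses import replace

        cfg = replace(cfg, kinematics_low=Kinematics(aim_spread_sd=6.0),
                      truth_low=StateTruth(threshold=8.0, slope=0.8, lapse=0.10))
        session, _ = generate_session(cfg)
        slices = [s for s in segment_trials(session) if s.include_flag]
        local = local_path_reliability(slices, cfg.geometry, PARAMS)
        original = bimodality_coefficient(local[~np.isnan(local)])
        control = error_reassignment_control(slices, cfg.geometry, PARAMS, seed=2)
        assert original.bc > 0.55
        assert control.bc > 0.55

    def test_missing_hits_on_one_side_rejected(self):
        trials = [path_slice(-10.0, side="left", outcome="distractor", trial_id=0),
                  path_slice(10.0, side="right", outcome="target", trial_id=1)]
        from vefkit.errors import UndefinedMetricError

        with pytest.raises(UndefinedMetricError):
            error_reassignment_control(trials, GEOM, PARAMS, seed=0)


class TestSmoothedCorrelations:
    def make_table(self, n, local_pr, metrics):
        df = pd.DataFrame({"trial_id": np.arange(n), "include_flag": True,
                           "local_pr": local_pr, "duration": 8.0})
        for k, v in metrics.items():
            df[k] = v
        for k in ("hit_index", "target_distance", "reaction_time",
                  "path_surplus", "lick_position", "running_speed"):
            if k not in df.columns:
                df[k] = 0.0
        return df

    def test_self_correlation_is_one(self, rng):
        n = 200
        lp = rng.normal(3, 1, n)
        sm = pd.Series(lp).rolling(25, center=True, min_periods=25).mean().to_numpy()
        # metric whose smoothed trace equals the local-PR trace by construction
        table = self.make_table(n, sm, {"hit_index": lp})
        r = smoothed_metric_correlations(table)
        assert r["hit_index"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_is_uncorrelated(self):
        exceed = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 500
            table = self.make_table(n, r.normal(3, 1, n), {"reaction_time": r.normal(0.5, 0.1, n)})
            out = smoothed_metric_correlations(table)
            exceed += abs(out["reaction_time"]) >= 0.2
        assert exceed <= 1

    def test_state_coupled_rt_correlates_negatively(self):
        cfg = benchmarks.satt_config(0.5, n_trials=400, seed=8)
        session, _ = generate_session(cfg)
        table = compute_metric_table(session)
        out = smoothed_metric_correlations(table)
        # the low-alert state carries slower reaction times by construction
        assert out["reaction_time"] < 0

    def test_too_few_trials_rejected(self, rng):
        from vefkit.errors import UndefinedMetricError

        table = self.make_table(10, rng.normal(3, 1, 10), {})
        with pytest.raises(UndefinedMetricError):
            smoothed_metric_correlations(table)
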