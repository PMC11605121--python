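import numpy as np
import pandas as pd
import pytest

from gaitfall.fixtures import FixtureSpec, make_kinematic_walker
from gaitfall.metrics import (DOUBLE_SUPPORT, InsufficientDataError,
                              clearance_metrics, compute_mos,
                              detect_gait_events, stride_metrics,
                              summarize_gait, traction_series)
from gaitfall.trajectory import REQUIRED_COLUMNS, Trajectory


def _mini_trajectory(n=100, dt=0.01, **overrides):
    """Constant-channel trajectory for unit-level MOS/traction checks."""
    t = np.arange(n) * dt
    cols = {c: np.zeros(n) for c in REQUIRED_COLUMNS}
    cols["t"] = t
    cols["com_y"] = np.full(n, 1.0)
    cols["hip_y"] = np.full(n, 0.92)
    # both feet loaded: continuous double support
    for pt in ("heel_r", "toe_r", "heel_l", "toe_l"):
        cols[f"fgy_{pt}"] = np.full(n, 200.0)
    cols.update({k: (np.full(n, v) if np.isscalar(v) else v)
                 for k, v in overrides.items()})
    return Trajectory(pd.DataFrame(cols))


class TestMosHandCases:
    def test_zero_velocity_case(self):
        # X=0.5, V=0 -> XCoM=0.5; borders 0.7 / 0.3 -> both margins 0.2
        traj = _mini_trajectory(com_x=0.5, com_vx=0.0,
                                toe_r_x=0.7, toe_l_x=0.7,
                                heel_r_x=0.3, heel_l_x=0.3)
        ev = detect_gait_events(traj)
        mos = compute_mos(traj, ev, l=1.0)
        assert mos.xcom[10] == pytest.approx(0.5, abs=1e-12)
        assert mos.anterior_mos[10] == pytest.approx(0.2, abs=1e-4)
        assert mos.posterior_mos[10] == pytest.approx(0.2, abs=1e-4)

    def test_forward_velocity_case(self):
        # X=0.5, V=0.3, l=1, g=9.81: XCoM = 0.5 + 0.3/sqrt(9.81) = 0.59578
        traj = _mini_trajectory(com_x=0.5, com_vx=0.3,
                                toe_r_x=0.7, toe_l_x=0.7,
                                heel_r_x=0.3, heel_l_x=0.3)
        ev = detect_gait_events(traj)
        mos = compute_mos(traj, ev, l=1.0, g=9.81)
        assert mos.xcom[5] == pytest.approx(0.59578, abs=1e-4)
        assert mos.anterior_mos[5] == pytest.approx(0.10422, abs=1e-4)

    def test_xcom_on_border_gives_zero_margin(self):
        traj = _mini_trajectory(com_x=0.7, com_vx=0.0,
                                toe_r_x=0.7, toe_l_x=0.7,
                                heel_r_x=0.3, heel_l_x=0.3)
        ev = detect_gait_events(traj)
        mos = compute_mos(traj, ev, l=1.0)
        assert mos.anterior_mos[5] == pytest.approx(0.0, abs=1e-12)

    def test_sign_rule_equivalence_sample_wise(self):
        traj, _ = make_kinematic_walker(FixtureSpec(noise_sd=0.02, seed=4))
        ev = detect_gait_events(traj)
        mos = compute_mos(traj, ev)
        unstable_fwd = mos.anterior_mos < 0
        outside_fwd = mos.xcom > mos.anterior_border
        np.testing.assert_array_equal(unstable_fwd, outside_fwd)
        inside = (mos.xcom >= mos.posterior_border) & (mos.xcom <= mos.anterior_border)
        both_pos = (mos.anterior_mos >= 0) & (mos.posterior_mos >= 0)
        np.testing.assert_array_equal(inside, both_pos)


class TestEventDetection:
    def test_square_wave_transitions_recovered(self):
        n = 2500
        t = np.arange(n) * 0.001
        fgy = np.where((t % 1.0) < 0.6, 400.0, 0.0)
        traj = _mini_trajectory(n=n, dt=0.001, fgy_heel_r=fgy / 2, fgy_toe_r=fgy / 2)
        ev = detect_gait_events(traj)
        # programmed liftoffs at 0.6, 1.6 s and touchdowns at 1.0, 2.0 s
        assert np.allclose(ev.liftoff_r, [0.6, 1.6], atol=0.002)
        assert np.allclose(ev.touchdown_r, [1.0, 2.0], atol=0.002)

    def test_standing_still_is_continuous_double_support(self):
        traj = _mini_trajectory()
        ev = detect_gait_events(traj)
        assert len(ev.touchdown_r) == 0 and len(ev.liftoff_r) == 0
        assert np.all(ev.phase == DOUBLE_SUPPORT)

    def test_threshold_events_match_programmed_contact_flags(self):
        traj, _ = make_kinematic_walker(FixtureSpec(seed=1, noise_sd=0.0))
        ev = detect_gait_events(traj)
        flags = traj.grf_y("r") > 0  # fixture writes exact square waves
        t = traj.t
        td_flags = t[1:][~flags[:-1] & flags[1:]]
        assert len(ev.touchdown_r) == len(td_flags)
        np.testing.assert_allclose(ev.touchdown_r, td_flags, atol=0.005)

    def test_empty_trajectory_rejected(self):
        with pytest.raises((InsufficientDataError, ValueError)):
            detect_gait_events(_mini_trajectory(n=2))


class TestParameterRecovery:
    def test_recovery_across_random_noiseless_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            sl = rng.uniform(0.6, 1.6)
            sp = rng.uniform(0.5, 1.5)
            mtc = rng.uniform(0.005, 0.040)
            spec = FixtureSpec(stride_length=sl, walking_speed=sp,
                               min_toe_clearance=mtc, n_strides=6,
                               noise_sd=0.0, seed=int(rng.integers(1 << 30)))
            traj, _ = make_kinematic_walker(spec)
            ev = detect_gait_events(traj)
            sm = stride_metrics(traj, ev)[1:-1]
            cl = clearance_metrics(traj, ev).iloc[1:-1]
            assert np.allclose([s.stride_length for s in sm], sl, rtol=0.02)
            assert np.allclose([s.walking_speed for s in sm], sp, rtol=0.02)
            assert np.allclose(cl["min_toe_clearance"], mtc, rtol=0.02)

    def test_noisy_fixture_stride_cv_recovered(self):
        spec = FixtureSpec(n_strides=200, noise_sd=0.05, seed=21)
        traj, truth = make_kinematic_walker(spec)
        ev = detect_gait_events(traj)
        sm = stride_metrics(traj, ev)
        sl = np.array([s.stride_length for s in sm])
        cv = 100 * sl.std(ddof=1) / sl.mean()
        assert cv == pytest.approx(5.0, abs=1.0)


class TestSummary:
    def test_identical_strides_have_zero_cv(self):
        traj, _ = make_kinematic_walker(FixtureSpec(noise_sd=0.0, n_strides=13))
        ev = detect_gait_events(traj)
        sm = stride_metrics(traj, ev)
        cl = clearance_metrics(traj, ev)
        summ = summarize_gait(sm, cl, n=10, start=1)
        for v in summ.cv.values():
            assert v == pytest.approx(0.0, abs=0.05)

    def test_alternating_strides_hand_computed_cv(self):
        # values {0.9, 1.1} x5: mean 1.0, sample SD 0.10541, CV 10.54%
        from gaitfall.metrics import StepMetrics, GaitSummary
        strides = [type("S", (), {})() for _ in range(10)]
        vals = [0.9, 1.1] * 5
        sm = []
        for i, v in enumerate(vals):
            sm.append(StepMetrics(index=i, t_start=float(i),
                                  stride_length=v, stride_time=1.0,
                                  walking_speed=v, cadence=1.0))
        cl = pd.DataFrame(dict(min_toe_clearance=np.full(10, 0.02),
                               max_heel_clearance=np.full(10, 0.3)))
        summ = summarize_gait(sm, cl, n=10)
        assert summ.mean["stride_length"] == pytest.approx(1.0)
        expected_cv = 100 * np.std(vals, ddof=1) / np.mean(vals)
        assert summ.cv["stride_length"] == pytest.approx(expected_cv, rel=1e-12)

    def test_insufficient_strides_raise(self):
        traj, _ = make_kinematic_walker(FixtureSpec(noise_sd=0.0, n_strides=5))
        ev = detect_gait_events(traj)
        sm = stride_metrics(traj, ev)
        cl = clearance_metrics(traj, ev)
        with pytest.raises(InsufficientDataError):
            summarize_gait(sm, cl, n=10)


class TestDegenerateInputs:
    def test_time_reversed_walk_rejected(self):
        traj, _ = make_kinematic_walker(FixtureSpec(noise_sd=0.0))
        rev = traj.data.iloc[::-1].reset_index(drop=True).copy()
        rev["t"] = traj.data["t"].to_numpy()
        rev_traj = Trajectory(rev)
        ev = detect_gait_events(rev_traj)
        with pytest.raises(InsufficientDataError):
            stride_metrics(rev_traj, ev)


class TestTraction:
    def test_constant_forces_give_constant_ratio(self):
        traj = _mini_trajectory(fgx_heel_r=20.0, fgx_toe_r=20.0,
                                fgy_heel_r=100.0, fgy_toe_r=100.0)
        ev = detect_gait_events(traj)
        tr = traction_series(traj, ev)
        row = tr[tr["foot"] == "r"].iloc[0]
        assert row["max_traction"] == pytest.approx(0.2, abs=1e-12)

    def test_matches_brute_force_maximum(self, rng):
        n = 500
        fgy = rng.uniform(0, 300, n)
        fgx = rng.normal(0, 60, n)
        traj = _mini_trajectory(n=n, fgy_heel_r=fgy, fgx_heel_r=fgx,
                                fgy_toe_r=np.zeros(n), fgx_toe_r=np.zeros(n))
        ev = detect_gait_events(traj)
        tr = traction_series(traj, ev)
        ok = fgy > 1.0
        brute = np.max(np.abs(fgx[ok]) / fgy[ok])
        # the right foot loses contact whenever fgy dips below threshold;
        # take the max over all its stance rows
        best = tr[tr["foot"] == "r"]["max_traction"].max()
        assert best == pytest.approx(brute, rel=1e-9)
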