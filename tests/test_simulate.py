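"""Model worm: decision sigmoids, samplers, kinematics, trial protocol."""

import math

import numpy as np
import pytest

from acidnav.gradient import fit_gradient, make_parametric_gradient
from acidnav.simulate import (
    PUBLISHED_OPTIMUM,
    DecisionParams,
    SimConfig,
    WormState,
    apply_reorientation,
    decide,
    encounter_angle,
    initial_direction_cdf,
    normalize_heading,
    p_curve,
    p_reversal,
    run_cohort,
    run_trial,
    sample_initial_direction,
    sensor_position,
)

UNIFORM_ACID = fit_gradient([(-1000.0, 1.0000001), (1000.0, 1.0)])  # pH ~1 everywhere


class TestDecisionSigmoids:
    def test_midpoints(self):
        assert p_curve(4.3, PUBLISHED_OPTIMUM) == pytest.approx(0.5)
        assert p_reversal(2.7, PUBLISHED_OPTIMUM) == pytest.approx(0.5)

    def test_known_values(self):
        # direct evaluation of 1/(1+e^z)
        assert p_curve(6.0, PUBLISHED_OPTIMUM) == pytest.approx(1 / (1 + math.exp(3.4)))
        assert p_curve(6.0, PUBLISHED_OPTIMUM) == pytest.approx(0.0323, abs=1e-4)
        assert p_reversal(4.0, PUBLISHED_OPTIMUM) == pytest.approx(1 / (1 + math.exp(2.6)))
        assert p_reversal(4.0, PUBLISHED_OPTIMUM) == pytest.approx(0.0691, abs=1e-4)

    def test_limits_and_saturation(self):
        assert p_curve(-1000.0, PUBLISHED_OPTIMUM) == 1.0
        assert p_curve(1000.0, PUBLISHED_OPTIMUM) == 0.0
        assert 0.0 < p_curve(7.5, PUBLISHED_OPTIMUM) < 1.0

    def test_strictly_decreasing(self):
        cs = np.linspace(1.0, 8.0, 60)
        pc = [p_curve(c, PUBLISHED_OPTIMUM) for c in cs]
        pr = [p_reversal(c, PUBLISHED_OPTIMUM) for c in cs]
        assert all(a > b for a, b in zip(pc, pc[1:]))
        assert all(a > b for a, b in zip(pr, pr[1:]))

    def test_shifted_sigmoid_ordering(self):
        # beta_r < beta_c with equal alphas => reversal less likely everywhere
        for c in np.linspace(1.0, 7.0, 25):
            assert p_reversal(c, PUBLISHED_OPTIMUM) < p_curve(c, PUBLISHED_OPTIMUM)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DecisionParams(-0.5, 4.3, 0.5, 2.7, 30, 10)
        with pytest.raises(ValueError):
            DecisionParams(0.5, 4.3, 0.5, 2.7, 30, -1)
        with pytest.warns(UserWarning):
            DecisionParams(0.5, 2.7, 0.5, 4.3, 30, 10)  # inverted thresholds


class TestInitialDirection:
    def test_range_and_symmetry(self, rng):
        draws = np.array([sample_initial_direction(rng) for _ in range(20000)])
        assert (draws > -90).all() and (draws <= 90).all()
        assert abs(draws.mean()) < 1.0  # even density

    def test_central_mass_matches_analytic_integral(self, rng):
        # P(|theta| <= 30) = (pi/3 - 2(1-cos 30)) / (pi - 2) = 0.68261
        draws = np.array([sample_initial_direction(rng) for _ in range(100000)])
        p = (np.abs(draws) <= 30.0).mean()
        expected = (np.pi / 3 - 2 * (1 - np.cos(np.pi / 6))) / (np.pi - 2)
        assert p == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 1e5))

    def test_cdf_endpoints(self):
        assert initial_direction_cdf(-90.0) == pytest.approx(0.0, abs=1e-12)
        assert initial_direction_cdf(0.0) == pytest.approx(0.5)
        assert initial_direction_cdf(90.0) == pytest.approx(1.0)


class TestSensor:
    def test_straight_ahead(self):
        cfg = SimConfig(sensor_swing_deg=0.0)
        state = WormState(x=0.0, y=0.0, heading_deg=0.0, swing_side="left")
        sx, sy = sensor_position(state, cfg)
        assert (sx, sy) == pytest.approx((0.51, 0.0))

    def test_right_swing_sign_convention(self):
        cfg = SimConfig(sensor_swing_deg=30.0)
        state = WormState(heading_deg=0.0, swing_side="right")
        sx, sy = sensor_position(state, cfg)
        assert sx == pytest.approx(0.51 * math.cos(math.radians(30)))
        assert sy == pytest.approx(-0.51 * math.sin(math.radians(30)))

    def test_sides_mirror(self):
        cfg = SimConfig()
        left = sensor_position(WormState(heading_deg=0.0, swing_side="left"), cfg)
        right = sensor_position(WormState(heading_deg=0.0, swing_side="right"), cfg)
        assert left[0] == pytest.approx(right[0])
        assert left[1] == pytest.approx(-right[1])


class TestDecide:
    def test_none_when_ph_far_above_centers(self, rng):
        assert all(decide(9.0, PUBLISHED_OPTIMUM, rng) is None for _ in range(2000))

    def test_outcome_frequencies_match_closed_form(self, rng):
        n = 100000
        p_r = p_reversal(4.0, PUBLISHED_OPTIMUM)
        p_c = p_curve(4.0, PUBLISHED_OPTIMUM)
        outcomes = [decide(4.0, PUBLISHED_OPTIMUM, rng) for _ in range(n)]
        f_rev = sum(o == "reversal" for o in outcomes) / n
        f_cur = sum(o == "curve" for o in outcomes) / n
        assert f_rev == pytest.approx(p_r, abs=3 * math.sqrt(p_r * (1 - p_r) / n))
        exp_cur = p_c * (1 - p_r)
        assert f_cur == pytest.approx(exp_cur, abs=3 * math.sqrt(exp_cur * (1 - exp_cur) / n))


class TestReorientation:
    def test_reversal_turn_moments(self, rng):
        cfg = SimConfig()
        mags = []
        for _ in range(100000):
            s = WormState(heading_deg=0.0)
            apply_reorientation(s, "reversal", PUBLISHED_OPTIMUM, cfg, rng)
            mags.append(abs(s.heading_deg))
        mags = np.array(mags)
        assert mags.mean() == pytest.approx(137.0, abs=3 * 8 / math.sqrt(len(mags)))
        assert mags.std(ddof=1) == pytest.approx(8.0, abs=0.15)

    def test_curve_turn_mean(self, rng):
        cfg = SimConfig()
        mags = []
        for _ in range(20000):
            s = WormState(heading_deg=0.0)
            apply_reorientation(s, "curve", PUBLISHED_OPTIMUM, cfg, rng, side_hint="left")
            mags.append(s.heading_deg)
        mags = np.array(mags)
        # side hint respected: left turns are positive except the N(30,10)
        # tail below zero, whose mass is Phi(-3) ~ 0.13%
        assert (mags > 0).mean() > 0.99
        assert mags.mean() == pytest.approx(30.0, abs=3 * 10 / math.sqrt(len(mags)))

    def test_degenerate_curve_spread(self, rng):
        params = DecisionParams(0.5, 4.3, 0.5, 2.7, 30.0, 0.0)
        cfg = SimConfig()
        for _ in range(10):
            s = WormState(heading_deg=5.0)
            apply_reorientation(s, "curve", params, cfg, rng, side_hint="right")
            assert s.heading_deg == pytest.approx(-25.0)

    def test_position_unchanged(self, rng):
        s = WormState(x=1.5, y=-0.5, heading_deg=10.0)
        apply_reorientation(s, "reversal", PUBLISHED_OPTIMUM, SimConfig(), rng)
        assert (s.x, s.y) == (1.5, -0.5)


class TestTrialProtocol:
    def test_strong_acid_triggers_immediate_reversal(self):
        # pH ~1 everywhere with sharp sigmoids: reversal saturates and wins the tie
        params = DecisionParams(0.125, 4.3, 0.125, 2.7, 30.0, 10.0)
        cfg = SimConfig(max_steps=50)
        results = [
            run_trial(UNIFORM_ACID, params, cfg, np.random.default_rng([3, i]))
            for i in range(200)
        ]
        assert all(r.maneuver == "reversal" for r in results if r.terminated == "escaped")
        assert sum(r.terminated == "escaped" for r in results) >= 195

    def test_unreachable_thresholds_hit_step_cap(self):
        params = DecisionParams(0.125, 0.5, 0.125, 0.1, 30.0, 10.0)  # centers below any field pH
        field = make_parametric_gradient(4.0, 0.5, 6.0, 6.0, 3.0)
        cfg = SimConfig(max_steps=200)
        res = run_trial(field, params, cfg, np.random.default_rng(0))
        assert res.terminated == "step_cap"
        assert res.maneuver is None

    def test_path_length_conservation(self, standard_field, sim_config):
        # in-place reorientations add no length: path = steps * speed * dt
        for i in range(5):
            res = run_trial(standard_field, PUBLISHED_OPTIMUM, sim_config, np.random.default_rng([7, i]))
            assert res.path_length_mm == pytest.approx(
                res.steps * sim_config.speed * sim_config.dt, rel=1e-12
            )
            assert res.elapsed_s == res.steps * sim_config.dt

    def test_initial_position_within_bounds(self, standard_field):
        cfg = SimConfig(init_x_max=-2.0, max_steps=1)
        for i in range(50):
            res = run_trial(standard_field, PUBLISHED_OPTIMUM, cfg, np.random.default_rng([11, i]))
            # one step of at most speed*dt from a start in [-3, -2)
            assert -3.2 < res.final_position[0] < -1.8


class TestCohort:
    def test_empty_cohort(self, standard_field, sim_config):
        df = run_cohort(0, standard_field, PUBLISHED_OPTIMUM, sim_config, seed=0)
        assert len(df) == 0

    def test_same_seed_identical(self, standard_field, sim_config):
        a = run_cohort(50, standard_field, PUBLISHED_OPTIMUM, sim_config, seed=42)
        b = run_cohort(50, standard_field, PUBLISHED_OPTIMUM, sim_config, seed=42)
        assert a.equals(b)

    def test_different_seeds_differ(self, standard_field, sim_config):
        a = run_cohort(50, standard_field, PUBLISHED_OPTIMUM, sim_config, seed=1)
        b = run_cohort(50, standard_field, PUBLISHED_OPTIMUM, sim_config, seed=2)
        assert not a.equals(b)

    def test_angles_in_range_and_all_terminate(self, optimum_cohort):
        assert ((optimum_cohort.angle_deg >= 0) & (optimum_cohort.angle_deg <= 90)).all()
        assert set(optimum_cohort.terminated) <= {"escaped", "step_cap"}

    def test_angle_dependent_choice_pattern(self, optimum_cohort):
        """Curves dominate shallow encounters, reversals dominate deep ones."""
        ev = optimum_cohort[optimum_cohort.terminated == "escaped"]
        shallow = ev[ev.angle_deg < 30]
        deep = ev[ev.angle_deg > 70]
        assert (shallow.maneuver == "curve").mean() > (shallow.maneuver == "reversal").mean()
        assert (deep.maneuver == "reversal").mean() > (deep.maneuver == "curve").mean()


@pytest.mark.parametrize(
    "heading, expected",
    [(0.0, 90.0), (90.0, 0.0), (-90.0, 0.0), (45.0, 45.0), (135.0, 45.0), (180.0, 90.0)],
)
def test_encounter_angle_folding(heading, expected):
    assert encounter_angle(heading) == pytest.approx(expected)


@pytest.mark.parametrize(
    "raw, wrapped", [(190.0, -170.0), (-190.0, 170.0), (180.0, 180.0), (360.0, 0.0)]
)
def test_heading_normalization(raw, wrapped):
    assert normalize_heading(raw) == pytest.approx(wrapped)
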