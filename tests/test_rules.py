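"""Unit tests for the plasticity-rule core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fplr.calcium import CalciumTrace
from fplr.rules import (
    BasinSpec,
    FPLRRule1D,
    FPLRRule2D,
    GBParams,
    ProteinGatedRule,
    SBCParams,
    ScalarRegion,
    StepFunction1D,
    Thresholds,
    classify_region,
    closed_form_weight,
    eval_step,
    fplr1d_delta,
    fplr2d_delta,
    gb_delta,
    gb_simplified_delta,
    integrate_rule,
    lookup_2d,
    protein_gated_delta,
    sbc_cadep_delta,
    sbc_decay_delta,
    sbc_linear_delta,
    validate_basins,
)


def const_trace(level, n, dt=1.0):
    return CalciumTrace(np.full(n, float(level)), dt)


class TestClassifyRegion:
    @pytest.mark.parametrize("ca,expected", [
        (0.5, "pre_depressive"),
        (1.0, "depressive"),      # lower bound included
        (1.2999, "depressive"),
        (1.3, "potentiative"),    # theta_P belongs to the upper region
        (5.0, "potentiative"),
    ])
    def test_half_open_convention(self, thresholds, ca, expected):
        assert classify_region(ca, thresholds) == expected

    def test_negative_calcium_rejected(self, thresholds):
        with pytest.raises(ValueError):
            classify_region(-0.1, thresholds)

    def test_extra_thresholds_give_indices(self):
        thr = Thresholds(1.0, 1.3, extra=(1.2, 2.0))
        # regions: [0,1), [1,1.2), [1.2,1.3), [1.3,2), [2,inf)
        assert classify_region(1.25, thr) == 2
        assert classify_region(2.5, thr) == 4

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(1.3, 1.0)
        with pytest.raises(ValueError):
            Thresholds(-1.0, 1.3)
        with pytest.raises(ValueError):
            Thresholds(1.0, 1.3, extra=(1.3,))


class TestStepFunction:
    def test_hard_lookup(self):
        f = StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0))
        assert eval_step(f, 0.2) == 0.5
        assert eval_step(f, 1.0) == 0.0
        assert eval_step(f, 1.3) == 1.0

    def test_soft_midpoint_at_threshold(self):
        f = StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0), sharpness=(80.0, 80.0))
        # at an isolated threshold the sigmoid contributes half its jump
        assert eval_step(f, 1.0) == pytest.approx((0.5 + 0.0) / 2, abs=1e-6)

    def test_soft_converges_to_hard(self):
        hard = StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0))
        soft = StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0),
                              sharpness=(1e6, 1e6))
        for ca in (0.5, 0.99, 1.01, 1.29, 1.31, 2.0):
            assert soft(ca) == pytest.approx(hard(ca), rel=1e-4)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            StepFunction1D((1.0,), (0.5,))
        with pytest.raises(ValueError):
            StepFunction1D((1.3, 1.0), (0.5, 0.0, 1.0))
        with pytest.raises(ValueError):
            StepFunction1D((1.0,), (0.5, 1.0), sharpness=(-3.0,))

    def test_vectorized_evaluation(self):
        f = StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0))
        np.testing.assert_allclose(f(np.array([0.2, 1.1, 2.0])),
                                   [0.5, 0.0, 1.0])


class TestSBC:
    @pytest.fixture
    def params(self, thresholds):
        return SBCParams(thresholds=thresholds, k_D=-1.0, k_P=1.0,
                         lambda_decay=0.5, eta=1.0)

    def test_linear_rule_is_weight_independent(self, thresholds):
        p = SBCParams(thresholds=thresholds, k_D=-1.0, k_P=1.0)
        assert sbc_linear_delta(0.5, p) == 0.0
        assert sbc_linear_delta(1.1, p) == -1.0
        zero = SBCParams(thresholds=thresholds, k_D=-1.0, k_P=1.0, eta=0.0)
        assert sbc_linear_delta(2.0, zero) == 0.0

    @pytest.mark.parametrize("ca,w", [
        (1.1, -2.0),   # depressive: w = k_D / lambda
        (0.5, 0.0),    # pre-depressive: decay fixed point 0
        (2.0, 2.0),    # potentiative: w = k_P / lambda
    ])
    def test_decay_fixed_points(self, params, ca, w):
        assert sbc_decay_delta(ca, w, params) == pytest.approx(0.0)

    def test_cadep_scales_with_eta_but_keeps_sign(self, thresholds):
        eta = StepFunction1D((1.0, 1.3), (0.01, 0.4, 0.8),
                             sharpness=(80.0, 80.0))
        p = SBCParams(thresholds=thresholds, k_D=-1.0, k_P=1.0,
                      lambda_decay=0.5, eta=eta)
        lo = sbc_cadep_delta(1.05, 1.0, p)
        hi = sbc_cadep_delta(1.25, 1.0, p)
        assert lo < 0 and hi < 0 and abs(hi) > abs(lo)
        # at the fixed point the update vanishes for any eta
        assert sbc_cadep_delta(1.25, p.omega(1.25) / 0.5, p) == pytest.approx(
            0.0, abs=1e-9)

    def test_invalid_signs_rejected(self, thresholds):
        with pytest.raises(ValueError):
            SBCParams(thresholds=thresholds, k_D=1.0, k_P=1.0)


class TestFPLR1D:
    def test_delta_examples(self, basic_rule):
        assert fplr1d_delta(2.0, 0.0, basic_rule) == pytest.approx(0.25)
        assert fplr1d_delta(1.1, 0.0, basic_rule) == 0.0  # at fixed point
        jump = FPLRRule1D(
            thresholds=basic_rule.thresholds,
            F=basic_rule.F,
            eta=StepFunction1D((1.0, 1.3), (0.0, 1.0, 1.0)),
        )
        w = 0.73
        assert w + fplr1d_delta(1.1, w, jump) == pytest.approx(0.0)

    def test_contraction_identity(self, basic_rule):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ca = rng.uniform(0, 2.5)
            w = rng.uniform(-1, 2)
            F = basic_rule.F(ca)
            frac = basic_rule.eta(ca) * basic_rule.dt
            w1 = w + fplr1d_delta(ca, w, basic_rule)
            assert abs(w1 - F) == pytest.approx((1 - frac) * abs(w - F),
                                                rel=1e-12, abs=1e-15)

    def test_eta_above_one_rejected(self, thresholds):
        with pytest.raises(ValueError):
            FPLRRule1D(
                thresholds=thresholds,
                F=StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0)),
                eta=StepFunction1D((1.0, 1.3), (0.0, 1.5, 0.25)),
            )


class TestClosedForm:
    def test_zero_elapsed_time_returns_w0(self, basic_rule):
        assert closed_form_weight(0.7, 2.0, 5.0, 5.0, basic_rule) == 0.7

    def test_half_life_identity(self, thresholds):
        # eta * (t_E - t_S) = ln 2 halves the distance to the fixed point
        rule = FPLRRule1D(
            thresholds=thresholds,
            F=StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0)),
            eta=StepFunction1D((1.0, 1.3), (0.0, 0.5, 0.25)),
            dt=1e-6,
        )
        eta_cont = -math.log1p(-0.5 * 1e-6) / 1e-6
        t = math.log(2) / eta_cont
        assert closed_form_weight(1.0, 1.1, 0.0, t, rule) == pytest.approx(0.5)

    def test_inverted_times_rejected(self, basic_rule):
        with pytest.raises(ValueError):
            closed_form_weight(1.0, 2.0, 5.0, 4.0, basic_rule)

    def test_matches_discrete_integration(self, basic_rule):
        n = 500
        trace = const_trace(1.1, n, dt=basic_rule.dt)
        traj = integrate_rule(trace, 1.0, basic_rule)
        cf = closed_form_weight(1.0, 1.1, 0.0, n * basic_rule.dt, basic_rule)
        assert traj.final == pytest.approx(cf, rel=1e-8)


class TestGB:
    @pytest.fixture
    def params(self, thresholds):
        return GBParams(thresholds=thresholds, w_star=0.5, eta_D=1.0,
                        eta_P=2.0, tau=10.0)

    @pytest.mark.parametrize("w", [0.0, 0.5, 1.0])
    def test_cubic_roots_in_pre_depressive(self, params, w):
        assert gb_delta(0.5, w, params) == 0.0

    def test_drift_value(self, params):
        # tau * dw = -w (1 - w)(w* - w) at w = 0.25
        assert params.tau * gb_delta(0.5, 0.25, params) == pytest.approx(
            -0.25 * 0.75 * 0.25)

    def test_saturated_weight_still_depresses(self, params):
        # at w = 1 the drift and potentiation terms vanish: tau dw = -eta_D
        assert params.tau * gb_delta(2.0, 1.0, params) == pytest.approx(
            -params.eta_D)

    def test_cumulative_terms_in_depressive(self, params):
        w = 0.3
        drift = -w * (1 - w) * (params.w_star - w)
        assert params.tau * gb_delta(1.1, w, params) == pytest.approx(
            drift - params.eta_D * w)

    def test_pure_drift_when_rates_zero(self, thresholds):
        p = GBParams(thresholds=thresholds, w_star=0.4, eta_D=0.0, eta_P=0.0,
                     tau=1.0)
        for ca in (0.2, 1.1, 2.0):
            for w in (0.0, 0.4, 1.0):
                assert gb_delta(ca, w, p) == 0.0
            assert gb_delta(ca, 0.2, p) == pytest.approx(
                -0.2 * 0.8 * 0.2)


class TestGBSimplified:
    @pytest.fixture
    def params(self, thresholds):
        return GBParams(thresholds=thresholds, w_star=0.5, eta_D=0.1,
                        eta_P=0.2, eta_drift=0.01)

    def test_unstable_fixed_point(self, params):
        assert gb_simplified_delta(0.5, 0.5, params) == 0.0
        assert gb_simplified_delta(0.5, 0.49, params) < 0
        assert gb_simplified_delta(0.5, 0.51, params) > 0

    def test_potentiative_fixed_point_is_one(self, params):
        assert gb_simplified_delta(2.0, 1.0, params) == 0.0

    def test_depressive_branch(self, params):
        assert gb_simplified_delta(1.1, 0.4, params) == pytest.approx(-0.04)

    def test_single_branch_active(self, params):
        # in the potentiative region no drift/depression contributes
        assert gb_simplified_delta(2.0, 0.2, params) == pytest.approx(
            0.2 * 0.8)


class TestBasins:
    def test_valid_spec_ok(self):
        spec = BasinSpec((0.2, 0.5, 0.8), (0.0, 0.3, 0.7, 1.0),
                         (0.01, 0.01, 0.01))
        assert validate_basins(spec) == []

    def test_violations_reported_not_raised(self):
        spec = BasinSpec.__new__(BasinSpec)
        object.__setattr__(spec, "fixed_points", (0.8,))
        object.__setattr__(spec, "boundaries", (0.0, 0.3))
        object.__setattr__(spec, "learning_rates", (0.5,))
        object.__setattr__(spec, "boundary_stability", None)
        assert any("outside its basin" in v for v in validate_basins(spec))

        bad = BasinSpec.__new__(BasinSpec)
        object.__setattr__(bad, "fixed_points", (0.2, 0.5, 0.8))
        object.__setattr__(bad, "boundaries", (0.0, 0.7, 0.3, 1.0))
        object.__setattr__(bad, "learning_rates", (0.1, 0.1, 0.1))
        object.__setattr__(bad, "boundary_stability", None)
        assert any("not strictly increasing" in v for v in validate_basins(bad))

    def test_constructor_rejects_invalid(self):
        with pytest.raises(ValueError):
            BasinSpec((0.8,), (0.0, 0.3), (0.5,))


class TestLookup2D:
    def test_basin_fixed_points(self, tristable_rule):
        assert lookup_2d(0.5, 0.25, tristable_rule)[0] == 0.2
        assert lookup_2d(0.5, 0.65, tristable_rule)[0] == 0.5
        assert lookup_2d(0.5, 0.75, tristable_rule)[0] == 0.8

    def test_boundary_is_unstable_fixed_point(self, tristable_rule):
        F, _ = lookup_2d(0.5, 0.3, tristable_rule)
        assert F == 0.3
        assert fplr2d_delta(0.5, 0.3, tristable_rule) == 0.0

    def test_scalar_regions_reduce_to_1d(self, tristable_rule):
        assert lookup_2d(2.0, 0.4, tristable_rule) == (1.0, 0.25)

    def test_out_of_range_weight(self, tristable_rule):
        with pytest.raises(ValueError):
            lookup_2d(0.5, 1.5, tristable_rule)

    def test_middle_state_is_fixed(self, tristable_rule):
        assert fplr2d_delta(0.5, 0.5, tristable_rule) == 0.0

    def test_drift_direction_in_upper_basin(self, tristable_rule):
        assert fplr2d_delta(0.5, 0.75, tristable_rule) > 0  # toward 0.8


class TestProteinGating:
    @pytest.fixture
    def gated(self, basic_rule, tristable_rule):
        return ProteinGatedRule(no_protein_rule=basic_rule,
                                protein_rule=tristable_rule)

    def test_dispatch(self, gated, basic_rule, tristable_rule):
        assert protein_gated_delta(1.1, 0.6, 0, gated) == fplr1d_delta(
            1.1, 0.6, basic_rule)
        assert protein_gated_delta(0.5, 0.25, 1, gated) == fplr2d_delta(
            0.5, 0.25, tristable_rule)

    def test_invalid_protein_state(self, gated):
        with pytest.raises(ValueError):
            protein_gated_delta(1.1, 0.6, 2, gated)

    def test_shared_fixed_point_is_inert(self, gated):
        # depressive region fixed point 0 in both sub-rules
        assert protein_gated_delta(1.1, 0.0, 0, gated) == 0.0
        assert protein_gated_delta(1.1, 0.0, 1, gated) == 0.0


class TestIntegrateRule:
    def test_zero_rate_means_constant(self, thresholds):
        rule = FPLRRule1D(
            thresholds=thresholds,
            F=StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0)),
            eta=StepFunction1D((1.0, 1.3), (0.0, 0.0, 0.0)),
        )
        traj = integrate_rule(const_trace(1.1, 50), 0.77, rule)
        np.testing.assert_array_equal(traj.values, 0.77)

    def test_geometric_relaxation_exact(self, basic_rule):
        n = 300
        traj = integrate_rule(const_trace(2.0, n), 0.0, basic_rule)
        expected = 1.0 - np.power(0.75, np.arange(1, n + 1))
        np.testing.assert_allclose(traj.values, expected, rtol=1e-12)

    def test_fast_path_matches_stepwise_loop(self, basic_rule):
        # soft version of the same rule forces the generic per-step loop
        soft = FPLRRule1D(
            thresholds=basic_rule.thresholds,
            F=StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0), sharpness=(1e8, 1e8)),
            eta=StepFunction1D((1.0, 1.3), (0.015, 0.15, 0.25),
                               sharpness=(1e8, 1e8)),
        )
        rng = np.random.default_rng(3)
        ca = CalciumTrace(rng.uniform(0.2, 2.0, 400), 1.0)
        fast = integrate_rule(ca, 1.0, basic_rule)
        slow = integrate_rule(ca, 1.0, soft)
        np.testing.assert_allclose(fast.values, slow.values, rtol=1e-6)

    def test_step_protocol_dynamics(self, basic_rule):
        # potentiative step relaxes toward 1; after calcium removal the
        # weight drifts back toward the neutral state 0.5
        ca = np.concatenate([np.full(200, 2.0), np.zeros(2000)])
        traj = integrate_rule(CalciumTrace(ca, 1.0), 0.5, basic_rule)
        assert traj.values[199] == pytest.approx(1.0, abs=1e-3)
        assert traj.final == pytest.approx(0.5, abs=1e-3)
        assert np.all(np.diff(traj.values[200:]) <= 1e-15)

    def test_protein_trace_length_checked(self, basic_rule, tristable_rule):
        gated = ProteinGatedRule(basic_rule, tristable_rule)
        with pytest.raises(ValueError):
            integrate_rule(const_trace(1.1, 10), 0.5, gated,
                           protein_trace=np.ones(5, dtype=int))

    @given(w0=st.floats(-0.5, 1.5), seed=st.integers(0, 10_000),
           eta_vals=st.tuples(*[st.floats(0.0, 1.0)] * 3),
           f_vals=st.tuples(*[st.floats(-1.0, 2.0)] * 3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_containment_in_convex_hull(self, w0, seed, eta_vals, f_vals):
        """Trajectories never leave the hull of {w0} and the fixed points."""
        rule = FPLRRule1D(
            thresholds=Thresholds(1.0, 1.3),
            F=StepFunction1D((1.0, 1.3), f_vals),
            eta=StepFunction1D((1.0, 1.3), eta_vals),
        )
        rng = np.random.default_rng(seed)
        ca = CalciumTrace(rng.uniform(0, 2.5, 200), 1.0)
        traj = integrate_rule(ca, w0, rule)
        lo = min([w0] + list(f_vals))
        hi = max([w0] + list(f_vals))
        assert np.all(traj.values >= lo - 1e-12)
        assert np.all(traj.values <= hi + 1e-12)

    def test_2d_basin_convergence_and_confinement(self, tristable_rule):
        """Pre-depressive drift converges to the basin's own fixed point."""
        for w0, target, basin in ((0.05, 0.2, (0.0, 0.3)),
                                  (0.45, 0.5, (0.3, 0.7)),
                                  (0.95, 0.8, (0.7, 1.0))):
            traj = integrate_rule(const_trace(0.5, 2000), w0, tristable_rule)
            assert traj.final == pytest.approx(target, abs=1e-6)
            assert np.all(traj.values > basin[0] - 1e-12)
            assert np.all(traj.values < basin[1] + 1e-12)

    def test_gb_integration_drifts_bistably(self, thresholds):
        p = GBParams(thresholds=thresholds, w_star=0.5, eta_D=1.0, eta_P=1.0,
                     tau=10.0)
        up = integrate_rule(const_trace(0.5, 4000, dt=0.1), 0.7, p)
        down = integrate_rule(const_trace(0.5, 4000, dt=0.1), 0.3, p)
        assert up.final == pytest.approx(1.0, abs=1e-2)
        assert down.final == pytest.approx(0.0, abs=1e-2)
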