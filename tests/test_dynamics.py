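"""Steady-state model: promoter activities, read-through wiring, solvers."""

import numpy as np
import pytest

from grncontext.arrangements import TERMINATORS, TerminatorSpec, flip_arrangement, parse_label
from grncontext.dynamics import (
    CANONICAL_STATES,
    DoseResponseParams,
    InducerState,
    ModelParameters,
    apply_variant,
    lac_induction_curve,
    promoter_activity,
    readthrough_config,
    readthrough_inputs,
    rhs,
    steady_state,
    truth_table,
    truth_table_grid,
)

P_DEFAULT = ModelParameters(K=0.1)


class TestPromoterActivity:
    def test_fully_induced_gives_constitutive_rate(self):
        assert promoter_activity("P_lac", 5.0, 1.0, P_DEFAULT) == 1.0

    def test_no_repressor_gives_constitutive_rate(self):
        assert promoter_activity("P_tet", 0.0, 0.0, P_DEFAULT) == 1.0

    def test_half_repression_at_K(self):
        assert promoter_activity("P_lac", 0.1, 0.0, P_DEFAULT) == pytest.approx(0.5)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            promoter_activity("P_lac", -0.1, 0.0, P_DEFAULT)

    def test_clamped_at_zero_for_knockout(self):
        params = P_DEFAULT.with_(k_C=0.0)
        assert promoter_activity("P_tet", 1.0, 0.0, params) == 0.0


class TestReadthroughInputs:
    def test_all_forward_chain(self):
        a = parse_label("TLC")
        acts = [0.7, 0.5, 0.3]  # per-slot own activities: T, L, C
        r = readthrough_inputs(a, acts, (0.6, 0.6))
        assert r.rchi_T == 0.0  # slot 1, nothing upstream
        assert r.rchi_L == pytest.approx(0.6 * 0.7)  # from tetR
        assert r.rchi_C == pytest.approx(0.6 * 0.5)  # from lacI

    def test_opposite_orientation_blocks_readthrough(self):
        a = parse_label("T_rCL")  # cI forward in slot 2, upstream tetR reversed
        r = readthrough_inputs(a, [0.7, 0.5, 0.3], (0.6, 0.6))
        assert r.rchi_C == 0.0

    def test_reverse_tu_reads_from_the_right(self):
        a = parse_label("C_rL_rT_r")  # flip of TLC: same wiring
        r = readthrough_inputs(a, [0.3, 0.5, 0.7], (0.6, 0.6))
        assert r.rchi_T == 0.0
        assert r.rchi_L == pytest.approx(0.6 * 0.7)
        assert r.rchi_C == pytest.approx(0.6 * 0.5)

    def test_zero_rates_zero_inputs(self):
        a = parse_label("TLC")
        r = readthrough_inputs(a, [1.0, 1.0, 1.0], (0.0, 0.0))
        assert (r.rchi_L, r.rchi_T, r.rchi_C) == (0.0, 0.0, 0.0)

    def test_chain_term_crosses_two_junctions(self):
        a = parse_label("TLC")
        r = readthrough_inputs(a, [0.7, 0.5, 0.3], (0.5, 0.4), chain=True)
        assert r.rchi_C == pytest.approx(0.4 * 0.5 + 0.4 * 0.5 * 0.7)


class TestRhs:
    def test_induced_decoupled_fixed_point(self):
        a = parse_label("TLC")
        params = ModelParameters(K=0.1, mu=0.0)
        env = InducerState(1, 1)
        assert rhs((1.0, 1.0, 1.0), a, env, params) == pytest.approx((0, 0, 0))

    def test_rhs_vanishes_at_steady_state(self, fitted_params):
        a = parse_label("LTC")
        for env in CANONICAL_STATES:
            ss = steady_state(a, env, fitted_params)
            assert np.max(np.abs(rhs(ss.as_array(), a, env, fitted_params))) < 1e-9


class TestSteadyState:
    def test_all_induced_unit_point(self, tlc):
        ss = steady_state(tlc, InducerState(1, 1), ModelParameters(K=0.1, mu=0.0))
        assert (ss.L, ss.T, ss.C) == pytest.approx((1, 1, 1))
        assert ss.converged

    def test_iptg_only_closed_form(self, clt):
        # no read-through into cI, full P_lac induction: C = 1 - 1/(K+1)
        ss = steady_state(clt, InducerState(1, 0), ModelParameters(K=0.1, mu=0.0))
        assert (ss.L, ss.T) == pytest.approx((1.0, 1.0))
        assert ss.C == pytest.approx(1 - 1 / 1.1, abs=1e-9)

    def test_tlc_with_readthrough_closed_form(self, tlc):
        ss = steady_state(tlc, InducerState(1, 0), ModelParameters(K=0.1, mu=0.3))
        assert (ss.L, ss.T, ss.C) == pytest.approx((1.3, 1.0, 1 - 1 / 1.1 + 0.3), abs=1e-9)

    def test_integrator_matches_fixed_point(self, tlc, fitted_params):
        for env in CANONICAL_STATES:
            a = steady_state(tlc, env, fitted_params, method="ode").as_array()
            b = steady_state(tlc, env, fitted_params).as_array()
            assert np.max(np.abs(a - b)) < 1e-8


class TestTruthTable:
    def test_null_model_vector(self, null_params, all48):
        # mu=0 decouples neighbours: every arrangement gives the same vector
        expected = np.array([(np.sqrt(0.41) - 0.1) / 2, 1 - 1 / 1.1, 1.0, 1.0])
        for a in all48[::7]:
            assert truth_table(a, null_params).cI == pytest.approx(expected, abs=1e-9)

    def test_tlc_fitted_point_vector(self, tlc, fitted_params):
        assert truth_table(tlc, fitted_params).cI == pytest.approx(
            [0.4442, 0.6909, 1.1324, 1.6], abs=5e-4
        )

    def test_clt_iptg_value(self, clt, fitted_params):
        tt = truth_table(clt, fitted_params)
        assert tt.cI[1] == pytest.approx(1 - 1.6 / 1.7, abs=1e-9)

    def test_grid_path_matches_scalar_path(self, fitted_params, all48):
        for a in all48[::11]:
            grid = truth_table_grid(a, fitted_params.K, fitted_params.mu, fitted_params)
            scalar = truth_table(a, fitted_params).cI
            assert grid.ravel() == pytest.approx(scalar, abs=1e-10)


class TestModelProperties:
    def test_orientation_pair_symmetry(self, all48, fitted_params):
        for a in all48:
            b = flip_arrangement(a)
            assert readthrough_config(a) == readthrough_config(b)
            assert truth_table(a, fitted_params).cI == pytest.approx(
                truth_table(b, fitted_params).cI, abs=0
            )

    def test_cI_monotone_in_readthrough_into_cI(self, tlc):
        # junction 2 feeds cI in TLC; C must be non-decreasing in its rate
        rates = np.linspace(0, 1, 11)
        for env in CANONICAL_STATES:
            cs = []
            for r in rates:
                a = tlc.with_junction(1, TerminatorSpec("x", float(r), 0))
                cs.append(steady_state(a, env, ModelParameters(K=0.1, mu=0.6)).C)
            assert np.all(np.diff(cs) >= -1e-12)

    def test_init_condition_independence(self, rng, all48):
        # the cascade has a unique attractor: random starts agree with origin
        for _ in range(20):
            a = all48[rng.integers(48)]
            env = CANONICAL_STATES[rng.integers(4)]
            params = ModelParameters(
                K=float(10 ** rng.uniform(-3, 1)), mu=float(rng.uniform(0, 1))
            )
            ref = steady_state(a, env, params, method="ode").as_array()
            x0 = rng.uniform(0, 3, size=3)
            alt = steady_state(a, env, params, method="ode", x0=x0).as_array()
            assert np.max(np.abs(ref - alt)) < 1e-6

    def test_trajectories_stay_nonnegative(self, tlc, fitted_params, rng):
        from scipy.integrate import solve_ivp

        for env in CANONICAL_STATES:
            sol = solve_ivp(
                lambda t, y: rhs(y, tlc, env, fitted_params),
                (0, 50),
                np.zeros(3),
                method="LSODA",
                dense_output=True,
            )
            assert np.min(sol.y) > -1e-9


class TestVariants:
    def test_ptet_knockout_keeps_iptg_response(self, tlc, fitted_params):
        a, params = apply_variant(tlc, fitted_params, "ptet_minus10")
        tt_mut = truth_table(a, params)
        tt_wt = truth_table(tlc, fitted_params)
        # IPTG-state cI comes from read-through, so it is unchanged
        assert tt_mut.cI[1] == pytest.approx(tt_wt.cI[1] - (1 - 1 / 1.1), abs=1e-9)
        # aTc no longer switches the output anywhere near the wild-type way:
        # without P_tet the aTc state loses its induction jump
        assert tt_mut.cI[2] < tt_wt.cI[2]

    def test_terminator_swap_strong_reverts_to_null(self, tlc, fitted_params, null_params):
        from grncontext.phenotype import classify_model

        a, params = apply_variant(
            tlc, fitted_params, "terminator_swap", junction=1,
            spec=TerminatorSpec("off", 0.0, 0),
        )
        lbl = classify_model(truth_table(a, params).cI, tau=0.4)
        null_lbl = classify_model(truth_table(tlc, null_params).cI, tau=0.4)
        assert lbl == null_lbl == "NOT_aTc"

    def test_double_terminator_product(self, tlc, fitted_params):
        half = TerminatorSpec("A", 0.5, 0)
        a, params = apply_variant(
            tlc, fitted_params, "double_terminator", junction=1, spec=half, spec2=half
        )
        assert a.junctions[1].rate(params.mu) == pytest.approx(0.25)

    def test_unknown_variant_rejected(self, tlc, fitted_params):
        with pytest.raises(ValueError, match="unknown variant"):
            apply_variant(tlc, fitted_params, "nonsense")


class TestInductionCurve:
    CONCS = np.logspace(0, 3.5, 15)

    def test_monotone_in_concentration(self):
        curve = lac_induction_curve(0.5, 1.0, self.CONCS)
        assert np.all(np.diff(curve) >= -1e-12)

    def test_weaker_terminator_lowers_midrange(self):
        weak = lac_induction_curve(0.8, 1.0, self.CONCS)
        strong = lac_induction_curve(0.0, 1.0, self.CONCS)
        mid = slice(3, 11)
        assert np.all(weak[mid] < strong[mid])

    def test_endpoints_bound_the_curve(self):
        dose = DoseResponseParams()
        curve = lac_induction_curve(0.3, 1.0, [0.0, 1e9], dose=dose)
        inner = lac_induction_curve(0.3, 1.0, self.CONCS, dose=dose)
        assert np.all(inner >= curve[0] - 1e-12)
        assert np.all(inner <= curve[1] + 1e-12)
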