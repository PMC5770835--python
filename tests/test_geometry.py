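"""Backpropagated threshold, envelope, boundary functions, mesh."""

import math

import numpy as np
import pytest

from exactlif import (
    AffineSystem,
    ModelParameters,
    NeuronState,
    backpropagated_threshold,
    build_envelope_mesh,
    build_lif_exp_system,
    chord_g,
    critical_locus_point,
    envelope_b,
    envelope_domain,
    evolve_state,
    extrusion_point,
    line_f,
    make_propagator,
    mesh_no_spike_test,
    rheobase,
    threshold_hyperplane,
)
from exactlif.geometry import _pivot_solve, load_mesh, save_mesh


def three_current_system(params, taus2=5.0):
    """LIF with two synaptic currents (distinct time constants): a 3-D
    affine system used to exercise the generic-N code paths."""
    C, tau = params.C_m, params.tau_m
    A = np.array([
        [-1.0 / params.tau_s, 0.0, 0.0],
        [0.0, -1.0 / taus2, 0.0],
        [1.0 / C, 1.0 / C, -1.0 / tau],
    ])
    q = np.array([0.0, 0.0, params.I_e / C])
    return AffineSystem(A=A, q=q)


class TestThresholdHyperplane:
    def test_coefficients(self, params):
        hp = threshold_hyperplane(params, 2)
        np.testing.assert_allclose(hp.k, [0.0, 1.0])
        assert hp.kappa == 20.0

    def test_membership_convention(self, params):
        hp = threshold_hyperplane(params, 2)
        assert hp.value(np.array([123.0, 20.0])) == 0.0
        assert hp.below(np.array([123.0, 19.0]))
        assert not hp.below(np.array([0.0, 21.0]))


class TestBackpropagatedThreshold:
    def test_zero_lag_is_threshold(self, system_375, params_375):
        hp = backpropagated_threshold(system_375, params_375, 0.0)
        np.testing.assert_allclose(hp.k, [0.0, 1.0], atol=1e-15)
        assert hp.kappa == pytest.approx(20.0)

    @pytest.mark.parametrize("t", [0.1, 1.0, 4.0])
    def test_affine_term_closed_form(self, system_375, params_375, t):
        # kappa_t = theta - I_e tau/C (1 - e^{-t/tau})
        hp = backpropagated_threshold(system_375, params_375, t)
        p = params_375
        expect = p.theta - p.I_e * p.tau_m / p.C_m * (1 - math.exp(-t / p.tau_m))
        assert hp.kappa == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("t", [0.05, 0.7, 3.0, 9.0])
    def test_forward_propagation_oracle(self, system_375, params_375, rng, t):
        # any state on the lag-t plane reaches V = theta after time t
        hp = backpropagated_threshold(system_375, params_375, t)
        fw = make_propagator(system_375, t, params=params_375)
        for _ in range(20):
            I = rng.uniform(-1000, 1000)
            V = (hp.kappa - hp.k[0] * I) / hp.k[1]
            out = evolve_state(NeuronState(I=I, V=V), fw)
            assert out.V == pytest.approx(params_375.theta, abs=1e-9)

    def test_generic_matches_2d(self, system_375, params_375):
        hp2 = backpropagated_threshold(system_375, params_375, 1.3)
        # force the generic path via a trivially embedded 3-D system
        sys3 = three_current_system(params_375)
        hp3 = backpropagated_threshold(sys3, params_375, 1.3)
        # first current column coincides with the 2-D model's
        assert hp3.k[0] == pytest.approx(hp2.k[0], rel=1e-12)
        assert hp3.k[2] == pytest.approx(hp2.k[1], rel=1e-12)
        assert hp3.kappa == pytest.approx(hp2.kappa, rel=1e-12)


class TestExtrusion:
    def test_zero_lag_embeds_threshold(self, system_375, params_375):
        pt = extrusion_point(system_375, params_375, 80.0, 0.0)
        assert pt.I == pytest.approx(80.0)
        assert pt.V == pytest.approx(20.0)

    @pytest.mark.parametrize("t", [0.3, 2.0, 7.5])
    def test_round_trip(self, system_375, params_375, rng, t):
        x = rng.uniform(-500, 500)
        pt = extrusion_point(system_375, params_375, x, t)
        back = evolve_state(pt, make_propagator(system_375, t,
                                                params=params_375))
        assert back.I == pytest.approx(x, rel=1e-9, abs=1e-9)
        assert back.V == pytest.approx(params_375.theta, abs=1e-9)

    def test_current_component(self, system_375, params_375):
        # I-component of E(x, t) is e^{t/tau_s} x
        pt = extrusion_point(system_375, params_375, 60.0, 1.5)
        assert pt.I == pytest.approx(60.0 * math.exp(1.5 / 2.0), rel=1e-12)


class TestCriticalLocus:
    def test_starts_at_threshold_nullcline_intersection(self, system_375,
                                                        params_375):
        pt = critical_locus_point(system_375, params_375, None, 0.0)
        assert pt.I == pytest.approx(125.0)  # I_theta - I_e
        assert pt.V == pytest.approx(20.0)

    def test_degenerate_at_rheobase(self, params):
        p = params.replace(I_e=500.0)
        sys = build_lif_exp_system(p)
        for t in (0.0, 1.0, 5.0):
            pt = critical_locus_point(sys, p, None, t)
            assert pt.I == pytest.approx(0.0, abs=1e-9)
            assert pt.V == pytest.approx(20.0, abs=1e-9)

    @pytest.mark.parametrize("t", np.linspace(0.0, 5.0, 7).tolist())
    def test_tangency_to_backpropagated_plane(self, system_375, params_375,
                                              t):
        pt = critical_locus_point(system_375, params_375, None, t)
        hp = backpropagated_threshold(system_375, params_375, t)
        assert abs(hp.value(pt.as_vector())) <= 1e-9

    def test_extremum_property(self, system_375, params_375):
        # the locus is the (time-reversed) trajectory of the intersection of
        # threshold and V-nullcline: evolving Gamma(t) forward by t lands on
        # that intersection, where dV/dt = 0 and the voltage grazes theta
        p = params_375
        nullcline = critical_locus_point(system_375, p, None, 0.0)
        for t in (0.0, 0.2, 1.0, 3.0):
            pt = critical_locus_point(system_375, p, None, t)
            fwd = evolve_state(pt, make_propagator(system_375, t, params=p))
            assert fwd.I == pytest.approx(nullcline.I, abs=1e-8)
            assert fwd.V == pytest.approx(nullcline.V, abs=1e-8)
            dV = fwd.I / p.C_m - fwd.V / p.tau_m + p.I_e / p.C_m
            assert abs(dV) <= 1e-8

    def test_no_envelope_without_current_coupling(self, params):
        A = np.array([[-0.5, 0.0], [0.0, -0.1]])  # c = 0
        sys = AffineSystem(A=A, q=np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="critical points"):
            _pivot_solve(sys, params, None)

    def test_3d_locus_on_backpropagated_plane(self, params_375):
        sys3 = three_current_system(params_375)
        for t in (0.0, 0.8, 2.5):
            for y in (-200.0, 0.0, 300.0):
                pt = critical_locus_point(sys3, params_375, [y], t)
                hp = backpropagated_threshold(sys3, params_375, t)
                assert abs(hp.value(pt.as_vector())) <= 1e-9


class TestRheobase:
    def test_reference_value(self, params):
        assert rheobase(params) == 500.0

    def test_zero_threshold(self, params):
        assert rheobase(ModelParameters(theta=0.0, V_reset=-1.0)) == 0.0

    def test_linearity_in_capacitance(self, params):
        assert rheobase(params.replace(C_m=500.0)) == 2 * rheobase(params)


class TestEnvelope:
    H = 5.0

    def test_domain_bounds(self, params_375):
        dom = envelope_domain(params_375, self.H)
        assert dom.I_lo == pytest.approx(125.0)
        assert dom.I_hi == pytest.approx(125.0 * math.exp(self.H / 2.0))
        assert not dom.degenerate

    def test_domain_suprarheobase_sign_swap(self, params_600):
        dom = envelope_domain(params_600, self.H)
        assert dom.empty_below_threshold
        assert dom.I_hi == pytest.approx(-100.0)
        assert dom.I_lo == pytest.approx(-100.0 * math.exp(self.H / 2.0))

    def test_starts_at_threshold(self, params_375):
        dom = envelope_domain(params_375, self.H)
        assert envelope_b(dom.I_lo, params_375, self.H) == pytest.approx(20.0)

    def test_tangency_to_f(self, params_375):
        dom = envelope_domain(params_375, self.H)
        b_hi = envelope_b(dom.I_hi, params_375, self.H)
        f_hi = line_f(dom.I_hi, self.H, params_375)
        assert b_hi == pytest.approx(f_hi, abs=1e-9)
        # equal slopes: finite difference on both sides
        eps = 1e-4 * dom.I_hi
        db = (b_hi - envelope_b(dom.I_hi - eps, params_375, self.H)) / eps
        df = (f_hi - line_f(dom.I_hi - eps, self.H, params_375)) / eps
        assert db == pytest.approx(df, rel=1e-3)

    def test_parametric_consistency(self, system_375, params_375):
        # b(Gamma_I(t)) == Gamma_V(t) along the locus
        for t in np.linspace(0.0, self.H, 50):
            pt = critical_locus_point(system_375, params_375, None, float(t))
            assert envelope_b(pt.I, params_375, self.H) == pytest.approx(
                pt.V, abs=1e-9)

    def test_outside_domain_rejected(self, params_375):
        dom = envelope_domain(params_375, self.H)
        with pytest.raises(ValueError, match="domain"):
            envelope_b(dom.I_lo - 1.0, params_375, self.H)

    def test_degenerate_rejected(self, params):
        with pytest.raises(ValueError, match="rheobase"):
            envelope_b(1.0, params.replace(I_e=500.0), self.H)

    def test_below_threshold_subrheobase(self, params_375):
        dom = envelope_domain(params_375, self.H)
        for I in np.linspace(dom.I_lo, dom.I_hi, 200):
            assert envelope_b(float(I), params_375, self.H) <= 20.0 + 1e-12

    def test_above_threshold_suprarheobase(self, params_600):
        dom = envelope_domain(params_600, self.H)
        for I in np.linspace(dom.I_lo, dom.I_hi, 200):
            assert envelope_b(float(I), params_600, self.H) >= 20.0 - 1e-12

    def test_decreasing_factor(self, params):
        # (tau e^{t/tau} - tau_s e^{t/tau_s})/(tau - tau_s) <= 1 on [0, h],
        # equality only at t = 0
        tau, taus = params.tau_m, params.tau_s
        ts = np.linspace(0.0, self.H, 1000)
        fac = (tau * np.exp(ts / tau) - taus * np.exp(ts / taus)) / (tau - taus)
        assert fac[0] == pytest.approx(1.0)
        assert np.all(fac[1:] < 1.0)


class TestLineF:
    def test_zero_step_is_threshold(self, params_375):
        for I in (-500.0, 0.0, 800.0):
            assert line_f(I, 0.0, params_375) == pytest.approx(20.0)

    def test_two_code_paths(self, system_375, params_375, rng):
        # closed form vs solving the backpropagated hyperplane for V
        h = 2.7
        hp = backpropagated_threshold(system_375, params_375, h)
        for I in rng.uniform(-2000, 2000, 50):
            via_plane = (hp.kappa - hp.k[0] * I) / hp.k[1]
            assert line_f(float(I), h, params_375) == pytest.approx(
                via_plane, rel=1e-12)

    def test_forward_oracle_approaches_threshold(self, system_375,
                                                 params_375):
        h, I = 3.0, 400.0
        fw = make_propagator(system_375, h, params=params_375)
        for eps in (1e-3, 1e-6, 1e-9):
            V0 = line_f(I, h, params_375) - eps
            out = evolve_state(NeuronState(I=I, V=V0), fw)
            assert out.V < params_375.theta
            assert params_375.theta - out.V < eps  # e^{-h/tau} * eps


class TestChordG:
    H = 5.0

    def test_left_endpoint(self, params_375):
        dom = envelope_domain(params_375, self.H)
        assert chord_g(dom.I_lo, self.H, params_375) == pytest.approx(20.0)

    def test_right_endpoint_tangency(self, params_375):
        dom = envelope_domain(params_375, self.H)
        g = chord_g(dom.I_hi, self.H, params_375)
        assert g == pytest.approx(envelope_b(dom.I_hi, params_375, self.H),
                                  abs=1e-9)
        assert g == pytest.approx(line_f(dom.I_hi, self.H, params_375),
                                  abs=1e-9)

    def test_chord_below_envelope(self, params_375, rng):
        dom = envelope_domain(params_375, self.H)
        for I in rng.uniform(dom.I_lo, dom.I_hi, 500):
            assert chord_g(float(I), self.H, params_375) <= envelope_b(
                float(I), params_375, self.H) + 1e-9

    def test_concavity_of_envelope(self, params_375, rng):
        # chords between random envelope points stay below the curve
        dom = envelope_domain(params_375, self.H)
        for _ in range(10_000):
            Ia, Ib = sorted(rng.uniform(dom.I_lo, dom.I_hi, 2))
            if Ib - Ia < 1e-9:
                continue
            lam = rng.uniform()
            Im = lam * Ia + (1 - lam) * Ib
            chord = (lam * envelope_b(Ia, params_375, self.H)
                     + (1 - lam) * envelope_b(Ib, params_375, self.H))
            assert chord <= envelope_b(Im, params_375, self.H) + 1e-9

    def test_suprarheobase_sentinel(self, params_600):
        assert chord_g(0.0, self.H, params_600) == math.inf


class TestMesh:
    H = 5.0

    def test_2d_two_slices_reduce_to_chord(self, system_375, params_375):
        # n_t = 2 gives exactly the inequality set {V < theta, V < f, V < g}
        mesh = build_envelope_mesh(system_375, params_375, self.H, 2)
        assert mesh.inequalities.shape == (3, 3)
        rng = np.random.default_rng(7)
        for _ in range(300):
            I = rng.uniform(-200, 1500)
            V = rng.uniform(-30, 19.999)
            s = NeuronState(I=I, V=V)
            expect = (V < params_375.theta
                      and V < line_f(I, self.H, params_375)
                      and V < chord_g(I, self.H, params_375))
            assert mesh_no_spike_test(s, mesh) == expect

    def test_conservative_against_oracle(self, system_375, params_375, rng):
        from exactlif.detection import brute_force_max
        mesh = build_envelope_mesh(system_375, params_375, self.H, 9)
        I = rng.uniform(-500, 2000, 10_000)
        V = rng.uniform(-30, 19.999, 10_000)
        vmax = brute_force_max(I, V, self.H, params_375, n=2000)
        crosses = vmax >= params_375.theta - 1e-9
        passes = np.array([mesh_no_spike_test(NeuronState(I=i, V=v), mesh)
                           for i, v in zip(I, V)])
        # mesh-pass must imply the oracle found no crossing
        assert not np.any(passes & crosses)

    def test_refinement_monotone(self, system_375, params_375, rng):
        from exactlif.detection import brute_force_max
        I = rng.uniform(0.0, 1500.0, 2000)
        V = rng.uniform(0.0, 19.999, 2000)
        vmax = brute_force_max(I, V, self.H, params_375, n=2000)
        no_spike = vmax < params_375.theta - 1e-9
        prev_pass = None
        prev_undetermined = None
        for n_t in (2, 3, 5, 9, 17, 33):   # nested t-grids
            mesh = build_envelope_mesh(system_375, params_375, self.H, n_t)
            passes = np.array([mesh_no_spike_test(NeuronState(I=i, V=v), mesh)
                               for i, v in zip(I, V)])
            undetermined = int(np.sum(no_spike & ~passes))
            if prev_pass is not None:
                assert np.all(passes | ~prev_pass)  # true never flips false
                assert undetermined <= prev_undetermined
            prev_pass, prev_undetermined = passes, undetermined

    def test_3d_mesh_conservative(self, params_375, rng):
        sys3 = three_current_system(params_375)
        y_box = np.array([[-400.0, 800.0]])
        mesh = build_envelope_mesh(sys3, params_375, 2.0, 6, y_box=y_box,
                                   n_y=7)
        # dense-sampling oracle via the generic propagator on a shared grid
        from exactlif import make_propagator
        ts = np.linspace(0.0, 2.0, 801)
        maps = [make_propagator(sys3, float(t)) for t in ts]
        states = np.column_stack([
            rng.uniform(-400, 800, 1500),
            rng.uniform(-400, 800, 1500),
            rng.uniform(-30, 19.999, 1500),
        ])
        vmax = np.full(len(states), -np.inf)
        for pm in maps:
            vmax = np.maximum(vmax, states @ pm.M[-1] + pm.m[-1])
        crosses = vmax >= params_375.theta - 1e-6
        for s, crossing in zip(states, crosses):
            if mesh_no_spike_test(NeuronState(I=s[:2], V=s[2]), mesh):
                assert not crossing

    def test_3d_outside_ybox_undetermined(self, params_375):
        sys3 = three_current_system(params_375)
        mesh = build_envelope_mesh(sys3, params_375, 2.0, 4,
                                   y_box=np.array([[-100.0, 100.0]]),
                                   n_y=4)
        deep = NeuronState(I=np.array([0.0, 500.0]), V=-20.0)
        assert not mesh_no_spike_test(deep, mesh)

    def test_requires_ybox_above_2d(self, params_375):
        with pytest.raises(ValueError, match="y_box"):
            build_envelope_mesh(three_current_system(params_375), params_375,
                                2.0, 4)

    def test_export_import_round_trip(self, system_375, params_375,
                                      tmp_path):
        mesh = build_envelope_mesh(system_375, params_375, self.H, 5)
        path = tmp_path / "mesh.txt"
        save_mesh(mesh, path)
        loaded = load_mesh(path)
        np.testing.assert_allclose(loaded.inequalities, mesh.inequalities)
        assert loaded.h == mesh.h
        assert loaded.n_t == mesh.n_t
        assert loaded.params_hash == mesh.params_hash
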