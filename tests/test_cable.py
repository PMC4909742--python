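"""Cable solver: closed-form equivalences, moments, and the transient oracle."""

import math

import numpy as np
import pytest

from dendrocomp import cable
from dendrocomp import morphology as mo

from conftest import single_cable


def soma_only(rm=10e3, cm=1.0, area=452.0):
    return cable.assemble([], area, rm, rm, cm, 150.0)


def cable_model(length, diameter=1.0, rm=10e3, cm=1.0, ra=150.0,
                soma_area=1e-4, max_len=5.0):
    """Near-sealed proximal end: vanishing soma membrane."""
    m = single_cable(length=length, diameter=diameter, soma_area=soma_area)
    comps = mo.compartmentalize(m, max_len)
    return cable.assemble(comps, soma_area, rm, rm, cm, ra)


class TestAssemble:
    def test_soma_conductance_units(self):
        model = soma_only(rm=10e3, area=452.0)
        assert model.g_membrane[0] == pytest.approx(4.52e-10, rel=1e-12)

    def test_matrix_symmetric(self, wt_pop):
        comps = mo.fold_spines_all(mo.compartmentalize(wt_pop[0], 37.0), 2.0)
        model = cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        G = model.G.toarray()
        assert np.max(np.abs(G - G.T)) == 0.0

    def test_spine_fold_scales_membrane_linearly(self):
        m = single_cable(length=100.0)
        c1 = mo.fold_spines_all(mo.compartmentalize(m, 37.0), 1.0)
        c2 = mo.fold_spines_all(mo.compartmentalize(m, 37.0), 2.0)
        m1 = cable.assemble(c1, 452.0, 10e3, 10e3, 1.0, 150.0)
        m2 = cable.assemble(c2, 452.0, 10e3, 10e3, 1.0, 150.0)
        ratio = c2[0].q / c1[0].q
        assert m2.g_membrane[1:] == pytest.approx(m1.g_membrane[1:] * ratio)
        assert m2.c[1:] == pytest.approx(m1.c[1:] * ratio)
        # axial coupling follows the smooth cylinder: off-diagonals unchanged
        off1 = m1.G.toarray()[0, 1]
        off2 = m2.G.toarray()[0, 1]
        assert off1 == pytest.approx(off2)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            cable.assemble([], 452.0, -1.0, 10e3, 1.0, 150.0)


class TestDcSolve:
    def test_isopotential_input_resistance(self):
        model = soma_only(rm=10e3, area=452.0)
        assert cable.input_resistance(model) == pytest.approx(2212.389, abs=1e-2)

    def test_sealed_cable_cosh_profile(self):
        # one space constant long; injection at the distal compartment
        # midpoint; sealed far (soma) end via vanishing soma membrane
        lam = cable.space_constant_um(1.0, 10e3, 150.0)
        assert lam == pytest.approx(408.248, abs=1e-2)
        model = cable_model(length=lam, max_len=lam / 100)
        site = model.n_nodes - 1
        sol = cable.dc_solve(model, site)
        x0 = model.compartments[-1].midpoint_path_distance
        expected = 1.0 / math.cosh(x0 / lam)
        assert sol.u[0] / sol.u[site] == pytest.approx(expected, rel=5e-3)

    def test_discretization_error_shrinks_quadratically(self):
        lam = cable.space_constant_um(1.0, 10e3, 150.0)

        def tip_transfer_error(h):
            model = cable_model(length=lam, max_len=h)
            site = model.n_nodes - 1
            sol = cable.dc_solve(model, site)
            x0 = model.compartments[-1].midpoint_path_distance
            return abs(sol.u[0] / sol.u[site] - 1.0 / math.cosh(x0 / lam))

        e37, e9 = tip_transfer_error(37.0), tip_transfer_error(37.0 / 4)
        assert e37 < 5e-3
        assert e9 < e37 / 8  # better than O(h^2) would need

    def test_injection_node_is_maximum(self, wt_pop):
        comps = mo.fold_spines_all(mo.compartmentalize(wt_pop[0], 37.0), 2.0)
        model = cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        sol = cable.dc_solve(model, model.n_nodes // 2)
        assert np.argmax(sol.u) == model.n_nodes // 2
        assert np.all(sol.u > 0)

    def test_reciprocity(self, wt_pop):
        comps = mo.fold_spines_all(mo.compartmentalize(wt_pop[0], 37.0), 2.0)
        model = cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        rng = np.random.default_rng(0)
        nodes = rng.choice(model.n_nodes, size=6, replace=False)
        for i in nodes:
            for j in nodes:
                ui = cable.dc_solve(model, int(i)).u
                uj = cable.dc_solve(model, int(j)).u
                assert ui[j] == pytest.approx(uj[i], rel=1e-10)

    def test_charge_conservation(self, wt_pop):
        comps = mo.fold_spines_all(mo.compartmentalize(wt_pop[1], 37.0), 2.0)
        model = cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        for site in (0, model.n_nodes - 1):
            sol = cable.dc_solve(model, site)
            assert np.dot(model.g_membrane, sol.u) == pytest.approx(1.0, rel=1e-10)

    def test_attached_dendrite_lowers_input_resistance(self):
        bare = cable.input_resistance(soma_only())
        m = single_cable(length=100.0, soma_area=452.0)
        comps = mo.compartmentalize(m, 37.0)
        with_dend = cable.input_resistance(
            cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        )
        assert with_dend < bare


class TestAcSolve:
    def test_isopotential_impedance_rolloff(self):
        # tau = 17 ms at 50 Hz: |Z(f)|/|Z(0)| = 1/sqrt(1+(2 pi f tau)^2)
        model = soma_only(rm=8.5e3, cm=2.0)
        z50 = cable.ac_solve(model, 0, 50.0).v_complex[0]
        z0 = cable.ac_solve(model, 0, 0.0).v_complex[0]
        expected = 1.0 / math.sqrt(1.0 + (2 * math.pi * 50.0 * 17e-3) ** 2)
        assert abs(z50) / abs(z0) == pytest.approx(expected, abs=1e-4)

    def test_zero_frequency_matches_dc(self, wt_pop):
        comps = mo.fold_spines_all(mo.compartmentalize(wt_pop[2], 37.0), 2.0)
        model = cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        dc = cable.dc_solve(model, 3)
        ac = cable.ac_solve(model, 3, 0.0)
        assert np.max(np.abs(ac.v_complex - dc.u)) < 1e-12

    def test_ac_transfer_attenuates_more_than_dc(self):
        model = cable_model(length=300.0, soma_area=452.0, max_len=10.0)
        site = model.n_nodes - 1
        dc = cable.dc_solve(model, site)
        ac = cable.ac_solve(model, site, 50.0)
        vt_dc = dc.u[0] / dc.u[site]
        vt_50 = abs(ac.v_complex[0] / ac.v_complex[site])
        assert vt_50 <= vt_dc

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            cable.ac_solve(soma_only(), 0, -1.0)


class TestTimeConstant:
    def test_uniform_membrane_tau_is_rm_cm(self, wt_pop):
        comps = mo.fold_spines_all(mo.compartmentalize(wt_pop[0], 37.0), 2.0)
        model = cable.assemble(comps, 452.0, 8.5e3, 8.5e3, 2.0, 150.0)
        assert cable.system_time_constant(model) == pytest.approx(17.0, rel=1e-9)

    def test_isopotential_tau(self):
        assert cable.system_time_constant(soma_only(rm=8.5e3, cm=2.0)) == \
            pytest.approx(17.0, rel=1e-12)

    def test_nonuniform_tau_matches_transient_peel(self):
        # leaky-soma style model: eigenvalue route vs exponential tail of
        # the simulated somatic step response
        m = single_cable(length=300.0, soma_area=452.0)
        comps = mo.compartmentalize(m, 20.0)
        model = cable.assemble(comps, 452.0, 5e3, 50e3, 1.0, 150.0)
        tau_eig = cable.system_time_constant(model)
        t_stop = 10 * tau_eig * 1e-3
        times, V = cable.transient_oracle(model, 0, lambda t: 1e-12, t_stop,
                                          dt_s=0.05e-3)
        v = V[:, 0]
        v_inf = v[-1]
        # exponential peel on the late tail
        resid = v_inf - v
        i0 = np.searchsorted(times, 2 * tau_eig * 1e-3)
        i1 = np.searchsorted(times, 5 * tau_eig * 1e-3)
        slope = np.polyfit(times[i0:i1], np.log(resid[i0:i1]), 1)[0]
        tau_peel = -1e3 / slope
        assert tau_eig == pytest.approx(tau_peel, rel=0.01)


class TestCentroidDelays:
    def test_isopotential_local_delay_is_tau(self):
        model = soma_only(rm=8.5e3, cm=2.0)  # tau = 17 ms
        sol = cable.dc_solve(model, 0)
        local, prop = cable.centroid_delays(sol, soma=0)
        assert local == pytest.approx(17.0, rel=1e-12)
        assert prop == pytest.approx(0.0, abs=1e-12)

    def test_long_cable_delay_half_tau_per_space_constant(self):
        # in a long passive cable the centroid advances by tau/2 per unit
        # electrotonic distance between interior points; recording at a
        # sealed end the reflection shortens it to (tau/2) X tanh(X)
        tau_ms = 17.0
        rm, cm = 10e3, tau_ms / 10.0  # Rm*Cm = 17 ms
        lam = cable.space_constant_um(1.0, rm, 150.0)
        model = cable_model(length=8 * lam, rm=rm, cm=cm, max_len=lam / 50)
        mids = np.array([c.midpoint_path_distance for c in model.compartments])

        def node_at(x):
            return 1 + int(np.argmin(np.abs(mids - x)))

        # interior-to-interior, Delta X = 1, both points >= 3 lambda from ends
        site, rec = node_at(4 * lam), node_at(3 * lam)
        sol = cable.dc_solve(model, site)
        t_rec = 1e3 * sol.w[rec] / sol.u[rec]
        t_site = 1e3 * sol.w[site] / sol.u[site]
        dx = (mids[site - 1] - mids[rec - 1]) / lam
        assert t_rec - t_site == pytest.approx(tau_ms / 2 * dx, rel=0.02)

        # sealed-end recording at X = 1
        site = node_at(lam)
        sol = cable.dc_solve(model, site)
        _, prop = cable.centroid_delays(sol, soma=0)
        x = mids[site - 1] / lam
        assert prop == pytest.approx(tau_ms / 2 * x * math.tanh(x), rel=0.02)

    def test_delay_at_soma_is_zero(self):
        model = cable_model(length=200.0, soma_area=452.0)
        sol = cable.dc_solve(model, 0)
        _, prop = cable.centroid_delays(sol, soma=0)
        assert prop == pytest.approx(0.0, abs=1e-12)

    def test_moment_delays_match_transient_centroids(self):
        m = single_cable(length=300.0, soma_area=452.0)
        comps = mo.compartmentalize(m, 30.0)
        model = cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        site = model.n_nodes - 1
        sol = cable.dc_solve(model, site)
        local, prop = cable.centroid_delays(sol, soma=0)

        # brute force: brief pulse, numerical first-moment centroids
        pulse = 0.05e-3
        stim = lambda t: 1e-12 if t < pulse else 0.0
        times, V = cable.transient_oracle(model, site, stim, 0.15, dt_s=0.0125e-3)
        def centroid(v):
            return np.trapezoid(times * v, times) / np.trapezoid(v, times)
        c_in = pulse / 2
        local_tr = 1e3 * (centroid(V[:, site]) - c_in)
        prop_tr = 1e3 * (centroid(V[:, 0]) - centroid(V[:, site]))
        assert local == pytest.approx(local_tr, rel=0.02)
        assert prop == pytest.approx(prop_tr, rel=0.02)


class TestTransientOracle:
    def test_step_response_closed_form(self):
        model = soma_only(rm=8.5e3, cm=2.0)
        R = cable.input_resistance(model) * 1e6
        tau = 17e-3
        I0 = 1e-12
        times, V = cable.transient_oracle(model, 0, lambda t: I0, 0.1, dt_s=0.025e-3)
        expected = I0 * R * (1 - np.exp(-times / tau))
        err = np.max(np.abs(V[:, 0] - expected)[1:] / (I0 * R))
        assert err < 5e-3

    def test_charge_ratio_matches_moment_solve(self):
        m = single_cable(length=60.0, soma_area=452.0)
        comps = mo.compartmentalize(m, 30.0)
        model = cable.assemble(comps, 452.0, 10e3, 10e3, 1.0, 150.0)
        site = model.n_nodes - 1
        sol = cable.dc_solve(model, site)
        ct = model.g_membrane[0] * sol.u[0]
        pulse = 0.05e-3
        stim = lambda t: 1e-12 if t < pulse else 0.0
        times, V = cable.transient_oracle(model, site, stim, 0.2, dt_s=0.0125e-3)
        q_soma = model.g_membrane[0] * np.trapezoid(V[:, 0], times)
        q_in = 1e-12 * pulse
        assert q_soma / q_in == pytest.approx(ct, rel=0.01)

    def test_centroid_converges_with_time_step(self):
        model = cable_model(length=200.0, soma_area=452.0, max_len=20.0)
        site = model.n_nodes - 1

        def centroid_at(dt):
            pulse = 0.05e-3
            stim = lambda t: 1e-12 if t < pulse else 0.0
            times, V = cable.transient_oracle(model, site, stim, 0.12, dt_s=dt)
            return np.trapezoid(times * V[:, 0], times) / np.trapezoid(V[:, 0], times)

        c1, c2 = centroid_at(0.025e-3), centroid_at(0.0125e-3)
        assert abs(c2 - c1) / c1 < 0.002

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            cable.transient_oracle(soma_only(), 0, lambda t: 0.0, 0.1, dt_s=0.0)
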