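"""Transfer metrics, site placement, comparison graphs, compensation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dendrocomp import cable, config, fitting, transfer
from dendrocomp import morphology as mo
from dendrocomp.fitting import MembraneModelSpec, FitResult

from conftest import single_cable


@pytest.fixture(scope="module")
def wt_records(wt_uniform_fits):
    recs = []
    for fr in wt_uniform_fits:
        recs.extend(transfer.compute_transfers(fr))
    return recs


def _cable_fit(length=300.0, diameter=1.0, rm=10e3, cm=1.0, soma_area=452.0,
               density=0.0):
    m = single_cable(length=length, diameter=diameter, soma_area=soma_area)
    spec = MembraneModelSpec("uniform", rm, rm, cm)
    model = fitting.build_model(m, spec, spine_density=density)
    return FitResult(
        neuron_id=f"cab{length:.0f}", group="WT", spec=spec,
        achieved_rin_mohm=cable.input_resistance(model),
        achieved_tau_ms=rm * cm * 1e-3, tau_per_unit_cm_ms=rm * 1e-3,
        iterations=0, morphology=m,
    ), model


class TestPlaceSites:
    def test_spacing_bound_is_37um_for_thick_high_rm_dendrite(self):
        # d=1 um, Rm/q = 5 kOhm*cm^2: lambda = 288.7 um, 0.2 lambda = 57.7
        # => the 37 um cap governs
        lam = cable.space_constant_um(1.0, 5e3, 150.0)
        assert lam == pytest.approx(288.675, abs=1e-2)
        fr, _ = _cable_fit(rm=5e3, density=0.0)
        model = transfer.place_sites(fr, spine_density=0.0)
        assert max(c.length for c in model.compartments) <= 37.0 + 1e-9

    def test_spacing_respects_both_bounds(self, wt_uniform_fits):
        for fr in wt_uniform_fits[:4]:
            model = transfer.place_sites(fr)
            lam = model.space_constants_um()
            for c in model.compartments:
                assert c.length <= 37.0 + 1e-9
                assert c.length <= 0.2 * lam[c.id] + 1e-9

    def test_site_weights_partition_arbor_area(self, wt_uniform_fits):
        fr = wt_uniform_fits[0]
        model = transfer.place_sites(fr)
        total = sum(c.q * c.A_d for c in model.compartments)
        mm = mo.morphometrics(fr.morphology, 2.0)
        expected = (mm["apical"]["area_incl_spines"]
                    + mm["basal"]["area_incl_spines"])
        assert total == pytest.approx(expected, rel=1e-9)


class TestComputeTransfers:
    def test_metric_ranges_and_frequency_ordering(self, wt_records):
        for r in wt_records:
            assert 0.0 < r.vt_dc <= 1.0
            assert 0.0 < r.ct <= 1.0
            assert r.vt_50 <= r.vt_dc + 1e-12
            assert r.local_delay_ms > 0.0
            assert r.propagation_delay_ms >= 0.0

    def test_vt_monotone_along_unbranched_cable(self):
        fr, _ = _cable_fit(length=400.0)
        recs = transfer.compute_transfers(fr)
        by_dist = sorted(recs, key=lambda r: r.path_distance_um)
        vts = [r.vt_dc for r in by_dist]
        assert all(a >= b for a, b in zip(vts, vts[1:]))

    def test_ct_matches_two_compartment_hand_solve(self):
        # soma + one compartment: G = [[gs+ga, -ga], [-ga, gd+ga]]
        fr, model = _cable_fit(length=30.0, rm=10e3)
        assert model.n_nodes >= 2
        recs = transfer.compute_transfers(fr, model)
        G = model.G.toarray()
        i = recs[0].site
        u = np.linalg.solve(G, np.eye(model.n_nodes)[:, i])
        assert recs[0].ct == pytest.approx(model.g_membrane[0] * u[0], rel=1e-12)

    def test_ct_matches_transient_charge_oracle(self):
        fr, _ = _cable_fit(length=90.0)
        m = fr.morphology
        comps = mo.compartmentalize(m, 30.0)  # 3 compartments
        model = cable.assemble(comps, m.soma_area, 10e3, 10e3, 1.0, 150.0)
        recs = transfer.compute_transfers(fr, model)
        site = recs[-1].site
        pulse = 0.05e-3
        stim = lambda t: 1e-12 if t < pulse else 0.0
        times, V = cable.transient_oracle(model, site, stim, 0.25, dt_s=0.0125e-3)
        q_soma = model.g_membrane[0] * np.trapezoid(V[:, 0], times)
        assert recs[-1].ct == pytest.approx(q_soma / (1e-12 * pulse), rel=0.01)

    def test_electrotonic_distance_on_uniform_cylinder(self):
        lam = cable.space_constant_um(1.0, 10e3, 150.0)  # 408.2 um
        fr, _ = _cable_fit(length=400.0, rm=10e3)
        model = transfer.place_sites(fr, spine_density=0.0)
        recs = transfer.compute_transfers(fr, model)
        for r in recs[::3]:
            assert r.electrotonic_distance == pytest.approx(
                r.path_distance_um / lam, rel=1e-9
            )


class TestComparisonGraphs:
    def test_group_against_itself_is_null(self, wt_records):
        g = transfer.comparison_graphs(wt_records, wt_records, "vt_dc")
        assert g.tested.sum() > 0
        assert g.percent_difference == 0.0

    def test_forced_shift_detected_everywhere(self, wt_records):
        shifted = [replace(r, vt_dc=r.vt_dc - 0.3) for r in wt_records]
        g = transfer.comparison_graphs(wt_records, shifted, "vt_dc")
        assert g.percent_difference == 100.0

    def test_bin_needs_enough_neurons(self, wt_records):
        g = transfer.comparison_graphs(wt_records, wt_records, "vt_dc", min_n=10**6)
        assert g.tested.sum() == 0
        assert math.isnan(g.percent_difference)

    def test_bootstrap_false_positive_rate(self, wt_uniform_fits):
        """Random half-splits of one population stay near the alpha level."""
        per_neuron = {
            fr.neuron_id: transfer.compute_transfers(fr) for fr in wt_uniform_fits
        }
        ids = sorted(per_neuron)
        rng = np.random.default_rng(0)
        sig = tested = 0
        for _ in range(20):
            perm = rng.permutation(ids)
            a = [r for i in perm[:5] for r in per_neuron[i]]
            b = [r for i in perm[5:] for r in per_neuron[i]]
            g = transfer.comparison_graphs(a, b, "vt_dc")
            sig += g.significant.sum()
            tested += g.tested.sum()
        assert tested > 0
        assert sig / tested <= 0.10


class TestSurfaceWeightedDistribution:
    def test_percentages_normalize_to_100(self, wt_records):
        out = transfer.surface_weighted_distribution(wt_records, wt_records, "ct")
        assert out["percent_a"].sum() == pytest.approx(100.0, abs=1e-6)
        assert out["percent_b"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_weight_scaling_invariance(self, wt_records):
        doubled = [replace(r, surface_weight_um2=2 * r.surface_weight_um2)
                   for r in wt_records]
        a = transfer.surface_weighted_distribution(wt_records, wt_records, "ct")
        b = transfer.surface_weighted_distribution(doubled, wt_records, "ct")
        assert np.allclose(a["percent_a"], b["percent_a"])

    def test_degenerate_metric_concentrates_in_one_bin(self, wt_records):
        const = [replace(r, ct=0.42) for r in wt_records]
        out = transfer.surface_weighted_distribution(const, const, "ct")
        assert out["percent_a"].max() == pytest.approx(100.0)


class TestNormalizeScales:
    def test_most_distal_site_maps_to_100(self, wt_records):
        normed = transfer.normalize_scales(wt_records)
        by_neuron = {}
        for r in normed:
            by_neuron.setdefault(r.neuron_id, []).append(r.path_distance_um)
        for dists in by_neuron.values():
            assert max(dists) == pytest.approx(100.0)

    def test_idempotent(self, wt_records):
        once = transfer.normalize_scales(wt_records)
        twice = transfer.normalize_scales(once)
        for a, b in zip(once, twice):
            assert a.vt_dc == pytest.approx(b.vt_dc)
            assert a.path_distance_um == pytest.approx(b.path_distance_um)

    def test_isoelectrotonic_scaling_invariance(self):
        """Lengths x k, diameters x k^2, soma x k^3: normalized voltage-
        transfer curves coincide (no spines, so q = 1)."""
        k = 1.5
        fr1, _ = _cable_fit(length=300.0, diameter=1.0, soma_area=452.0)
        fr2, _ = _cable_fit(length=300.0 * k, diameter=1.0 * k**2,
                            soma_area=452.0 * k**3)
        n1 = transfer.normalize_scales(
            transfer.compute_transfers(
                fr1, transfer.place_sites(fr1, spine_density=0.0,
                                          max_spacing_um=1e9))
        )
        n2 = transfer.normalize_scales(
            transfer.compute_transfers(
                fr2, transfer.place_sites(fr2, spine_density=0.0,
                                          max_spacing_um=1e9))
        )
        assert len(n1) == len(n2)
        for a, b in zip(n1, n2):
            assert a.path_distance_um == pytest.approx(b.path_distance_um, rel=1e-6)
            assert a.vt_dc == pytest.approx(b.vt_dc, rel=1e-6)


class TestCompensationAssessment:
    def test_no_membrane_change_never_compensates(self, wt_records):
        # TG' identical to TG: every needed range stays significantly
        # different in the WT-TG comparison as well
        tg = [replace(r, vt_dc=r.vt_dc - 0.3, group="TG") for r in wt_records]
        tgp = [replace(r, group="TG_PRIME") for r in tg]
        rep = transfer.compensation_assessment(
            wt_records, tg, tgp, metrics=("vt_dc",)
        )
        assert rep.overall_needed > 0
        assert rep.overall_success == 0
        assert rep.overall_rate == 0.0

    def test_full_compensation_scores_one(self, wt_records):
        # membrane scaling fully restores WT transfer curves: TG == WT,
        # while TG' (morphology effect alone) differs everywhere
        tg = [replace(r, group="TG") for r in wt_records]
        tgp = [replace(r, vt_dc=r.vt_dc - 0.3, group="TG_PRIME")
               for r in wt_records]
        rep = transfer.compensation_assessment(
            wt_records, tg, tgp, metrics=("vt_dc",)
        )
        assert rep.overall_needed > 0
        assert rep.overall_rate == pytest.approx(1.0)

    def test_rates_are_bounded(self, wt_records):
        rng = np.random.default_rng(5)
        tg = [replace(r, vt_dc=min(1.0, max(0.01, r.vt_dc + rng.normal(0, 0.1))),
                      group="TG") for r in wt_records]
        tgp = [replace(r, vt_dc=r.vt_dc - 0.2, group="TG_PRIME")
               for r in wt_records]
        rep = transfer.compensation_assessment(wt_records, tg, tgp,
                                               metrics=("vt_dc",))
        for row in rep.rows:
            if row.ranges_needed:
                assert 0.0 <= row.success_rate <= 1.0
            else:
                assert math.isnan(row.success_rate)
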