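"""Chemical-potential bookkeeping, molar fractions, pKa extraction,
state ladders and the explicit-site scheduler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmms.constants import LN10, kT
from vmms.protonation import (MolarFractionController, StateLadder,
                              deprotonation_delta_mu0,
                              equilibrium_molar_fractions,
                              implicit_site_charges, pka_equal_molar,
                              pka_from_fractions, titration_curve,
                              vmms_k_scheduler)
from vmms.topology import TitrationSite


def make_site(site_id="s1", pka_ref=7.0, dg_ref=0.0, x_d=0.5):
    return TitrationSite(site_id=site_id, atom_indices=np.array([0, 1]),
                         protonated_charges=np.array([-0.5, 0.4]),
                         deprotonated_charges=np.array([-1.1, 0.0]),
                         pka_ref=pka_ref, delta_g_ref=dg_ref,
                         x_deprotonated=x_d, dummy_atom=1)


class TestDeltaMu0:
    def test_reference_point_is_zero(self):
        assert deprotonation_delta_mu0(-3.0, 5.0, 5.0, -3.0, 300.0) == 0.0

    def test_one_ph_unit_above_pka(self):
        out = deprotonation_delta_mu0(0.0, 8.0, 7.0, 0.0, 300.0)
        assert out == pytest.approx(-kT(300.0) * LN10, rel=1e-12)
        # kT = 0.59616 kcal/mol at 300 K, times ln 10
        assert out == pytest.approx(-1.3727, abs=2e-4)

    def test_affine_in_ph(self):
        a = deprotonation_delta_mu0(1.0, 4.0, 7.0, 0.5, 300.0)
        b = deprotonation_delta_mu0(1.0, 6.0, 7.0, 0.5, 300.0)
        assert b - a == pytest.approx(-2 * kT(300.0) * LN10, rel=1e-12)


class TestEquilibriumFractions:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_zero_matrix_uniform(self, n):
        x = equilibrium_molar_fractions(np.zeros((n, n)), 300.0)
        np.testing.assert_allclose(x, np.full(n, 1 / n), rtol=1e-12)

    def test_two_state_boltzmann_ratio(self):
        dm = 0.8
        m = np.array([[0.0, dm], [-dm, 0.0]])
        x = equilibrium_molar_fractions(m, 300.0)
        assert x[1] / x[0] == pytest.approx(np.exp(-dm / kT(300.0)), rel=1e-10)

    def test_kt_ln2_two_thirds(self):
        dm = kT(300.0) * np.log(2.0)
        m = np.array([[0.0, dm], [-dm, 0.0]])
        x = equilibrium_molar_fractions(m, 300.0)
        assert x[1] / x[0] == pytest.approx(0.5, rel=1e-10)
        assert x[0] == pytest.approx(2 / 3, rel=1e-10)

    @given(st.integers(min_value=0, max_value=1000),
           st.integers(min_value=2, max_value=16))
    @settings(deadline=None, max_examples=50)
    def test_sums_to_one_random_antisymmetric(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-5, 5, size=(n, n))
        m = a - a.T
        x = equilibrium_molar_fractions(m, 300.0)
        assert x.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(x >= 0)

    def test_non_antisymmetric_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_molar_fractions(np.array([[0.0, 1.0], [1.0, 0.0]]),
                                        300.0)


class TestPka:
    def test_equal_fractions_pka_is_ph(self):
        assert pka_from_fractions(6.2, 0.4, 0.4) == pytest.approx(6.2)

    def test_nine_to_one(self):
        assert pka_from_fractions(7.0, 0.9, 0.1) == pytest.approx(7.9542, abs=1e-4)

    def test_swap_reflects_about_ph(self):
        up = pka_from_fractions(7.0, 0.8, 0.2)
        down = pka_from_fractions(7.0, 0.2, 0.8)
        assert up - 7.0 == pytest.approx(-(down - 7.0), rel=1e-12)

    def test_equal_molar_reference_point(self):
        assert pka_equal_molar(-3.0, -3.0, 9.1, 300.0) == pytest.approx(9.1)

    def test_equal_molar_unit_shift(self):
        dg = kT(300.0) * LN10
        assert pka_equal_molar(dg, 0.0, 4.0, 300.0) == pytest.approx(5.0)

    def test_roundtrip_fractions_pka_fractions(self):
        """x_H, x_D → pKa → equilibrium ratio at the same pH reproduces
        the input composition."""
        ph, x_d = 6.5, 0.23
        pka = pka_from_fractions(ph, 1 - x_d, x_d)
        # two-state equilibrium at the same pH with Δμ⁰ from that pKa
        dm = -kT(300.0) * (ph - pka) * LN10
        m = np.array([[0.0, dm], [-dm, 0.0]])
        x = equilibrium_molar_fractions(m, 300.0)
        assert x[1] == pytest.approx(x_d, rel=1e-9)


class TestImplicitCharges:
    def test_protonated_endpoint(self):
        site = make_site(x_d=0.0)
        np.testing.assert_array_equal(implicit_site_charges(site),
                                      site.protonated_charges)

    def test_deprotonated_endpoint(self):
        site = make_site(x_d=1.0)
        np.testing.assert_array_equal(implicit_site_charges(site),
                                      site.deprotonated_charges)

    def test_midpoint_arithmetic_mean(self):
        site = make_site(x_d=0.5)
        np.testing.assert_allclose(
            implicit_site_charges(site),
            0.5 * (site.protonated_charges + site.deprotonated_charges))


class TestStateLadder:
    def test_enumeration_and_labels(self):
        ladder = StateLadder([make_site("a"), make_site("b"), make_site("c")])
        assert ladder.n_states == 8
        assert ladder.labels(0) == (0, 0, 0)
        assert ladder.labels(5) == (1, 0, 1)
        assert ladder.state_index((1, 0, 1)) == 5

    def test_charge_sets_follow_bits(self):
        s1, s2 = make_site("a"), make_site("b")
        s2.atom_indices = np.array([2, 3])
        ladder = StateLadder([s1, s2])
        base = np.zeros(5)
        sets = ladder.charge_sets(base)
        np.testing.assert_array_equal(sets[0][:2], s1.protonated_charges)
        np.testing.assert_array_equal(sets[1][:2], s1.deprotonated_charges)
        np.testing.assert_array_equal(sets[2][2:4], s2.deprotonated_charges)

    def test_site_marginals(self):
        ladder = StateLadder([make_site("a"), make_site("b")])
        marg = ladder.site_marginals(np.array([0.1, 0.2, 0.3, 0.4]))
        np.testing.assert_allclose(marg, [0.6, 0.7])


class TestScheduler:
    def test_all_explicit_single_window(self):
        sites = [make_site(c) for c in "abc"]
        sched = list(vmms_k_scheduler(sites, 3, 10.0, 2.0))
        assert len(sched) == 1
        group, ladder, equil, prod = sched[0]
        assert group == (0, 1, 2)
        assert ladder.n_states == 8
        assert (equil, prod) == (2.0, 8.0)

    def test_round_robin_cycle(self):
        sites = [make_site(c) for c in "abc"]
        sched = list(vmms_k_scheduler(sites, 1, 10.0, 2.0, n_cycles=2))
        assert [g for g, *_ in sched] == [(0,), (1,), (2,)] * 2
        assert all(l.n_states == 2 for _, l, *_ in sched)

    def test_no_update_leaves_fractions(self):
        sites = [make_site("a", x_d=0.31), make_site("b", x_d=0.62)]
        list(vmms_k_scheduler(sites, 1, 10.0, 2.0))
        assert sites[0].x_deprotonated == 0.31
        assert sites[1].x_deprotonated == 0.62

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            list(vmms_k_scheduler([make_site()], 2, 10.0, 2.0))


class TestTitrationCurve:
    def test_exact_henderson_hasselbalch(self):
        ph = np.arange(3.0, 9.5, 0.5)
        runs = {p: 1.0 / (1.0 + 10 ** (6.0 - p)) for p in ph}
        out = titration_curve(runs)
        assert out["pka_hh"] == pytest.approx(6.0, abs=1e-3)
        assert out["pka_midpoint"] == pytest.approx(6.0, abs=0.05)

    def test_two_point_interpolation(self):
        out = titration_curve({5.0: 0.25, 7.0: 0.75})
        assert out["pka_midpoint"] == pytest.approx(6.0)

    def test_no_bracketing_raises(self):
        with pytest.raises(ValueError):
            titration_curve({5.0: 0.8, 7.0: 0.9})


class TestController:
    def test_reference_offsets_additive(self):
        s1 = make_site("a", pka_ref=6.0, dg_ref=-1.0)
        s2 = make_site("b", pka_ref=8.0, dg_ref=2.0)
        ladder = StateLadder([s1, s2])
        theta = ladder.reference_offsets(ph=7.0, temperature=300.0)
        t1 = kT(300.0) * (7.0 - 6.0) * LN10 - 1.0
        t2 = kT(300.0) * (7.0 - 8.0) * LN10 + 2.0
        np.testing.assert_allclose(theta, [0.0, t1, t2, t1 + t2], rtol=1e-12)

    def test_update_moves_towards_equilibrium(self):
        """With noiseless samples at ΔG = ΔG_ref and pH = pKa_ref the
        controller must settle at the symmetric composition."""
        from vmms.core import StateEnergyRecord
        site = make_site(pka_ref=7.0, dg_ref=0.0)
        ladder = StateLadder([site])
        ctrl = MolarFractionController(ladder, ph=7.0, temperature=300.0,
                                       window=1)
        rng = np.random.default_rng(0)
        recs = []
        for k in range(20):
            e = np.array([[0.0, 0.0], [0.0, 0.0]])
            recs.append(StateEnergyRecord(step=k, time=float(k),
                                          e_solute=e,
                                          e_solvent=np.zeros(2),
                                          e_pure=np.zeros(2),
                                          e_vmms=np.zeros(2),
                                          weights=np.ones(2),
                                          fractions=ladder.fractions.copy()))
        x = ctrl.update(recs)
        np.testing.assert_allclose(x, [0.5, 0.5], atol=1e-9)
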