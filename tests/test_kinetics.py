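"""Unit and property tests for the reaction-network core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclosim.errors import (InvalidInputError, NoSteadyStateError, StructuralError)
from cyclosim.kinetics import (
    CellModel, Compartment, CyclaseSource, TreatmentEffects, UNTREATED,
    assemble_rhs, exchange_flux, michaelis_menten_rate, pde_isoform,
    simulate_schedule, solve_steady_state, synthesis_rate,
)


class TestMichaelisMenten:
    def test_half_saturation_identity(self):
        # at S = Km the rate is exactly Vmax/2 (PDE8: Km 0.06 uM, Vmax 0.15)
        pde8 = pde_isoform("PDE8")
        assert michaelis_menten_rate(pde8, 0.06) == pytest.approx(0.075, rel=1e-14)

    @pytest.mark.parametrize("name", ["PDE4", "PDE8", "PDE5", "PDE2A"])
    def test_zero_substrate_zero_rate(self, name):
        iso = pde_isoform(name)
        nuc = "cGMP" if name in ("PDE5",) else "cAMP"
        assert michaelis_menten_rate(iso, 0.0, nucleotide=nuc) == 0.0

    def test_near_saturation_arithmetic(self):
        # PDE4 (Km 5, Vmax 0.03) at S = 495: 0.03 * 495/500 = 0.0297
        pde4 = pde_isoform("PDE4")
        assert michaelis_menten_rate(pde4, 495.0) == pytest.approx(0.0297, rel=1e-12)

    def test_saturating_and_monotone(self):
        pde4 = pde_isoform("PDE4")
        s = np.linspace(0, 100, 500)
        v = np.array([michaelis_menten_rate(pde4, x) for x in s])
        assert np.all(np.diff(v) > 0)
        assert v[-1] < pde4.vmax_local

    def test_inhibition_scales_linearly(self):
        pde4 = pde_isoform("PDE4")
        full = michaelis_menten_rate(pde4, 2.0)
        assert michaelis_menten_rate(pde4, 2.0, inhibition_fraction=0.25) == pytest.approx(0.75 * full)
        assert michaelis_menten_rate(pde4, 2.0, inhibition_fraction=1.0) == 0.0

    def test_invalid_inputs_raise(self):
        pde4 = pde_isoform("PDE4")
        with pytest.raises(InvalidInputError):
            michaelis_menten_rate(pde4, -1.0)
        with pytest.raises(InvalidInputError):
            michaelis_menten_rate(pde4, 1.0, activity_scalar=-0.1)
        with pytest.raises(InvalidInputError):
            michaelis_menten_rate(pde_isoform("PDE2A"), 1.0)  # dual needs nucleotide

    def test_low_substrate_efficiency_ratio(self):
        # catalytic efficiency Vmax/Km: PDE8 vs PDE4 = (0.15/0.06)/(0.03/5)
        pde8, pde4 = pde_isoform("PDE8"), pde_isoform("PDE4")
        s = 1e-12
        ratio = michaelis_menten_rate(pde8, s) / michaelis_menten_rate(pde4, s)
        assert ratio == pytest.approx((0.15 / 0.06) / (0.03 / 5.0), rel=1e-9)


class TestSynthesisRate:
    def test_untreated_identity(self):
        ac = CyclaseSource("cAMP", j_basal=0.01, max_stim_factor=5.0)
        assert synthesis_rate(ac) == pytest.approx(0.01)

    def test_ac_full_drive(self):
        ac = CyclaseSource("cAMP", j_basal=0.01, max_stim_factor=5.0)
        assert synthesis_rate(ac, TreatmentEffects(ac_drive=1.0)) == pytest.approx(0.05)

    def test_fully_oxidised_sgc_ignores_no(self):
        sgc = CyclaseSource("cGMP", j_basal=0.01, max_stim_factor=6.0,
                            oxidised_fraction=1.0)
        no_only = TreatmentEffects(reduced_sgc_drive=4.0)
        assert synthesis_rate(sgc, no_only) == pytest.approx(0.01)
        cin = TreatmentEffects(oxidised_sgc_drive=3.0)
        assert synthesis_rate(sgc, cin) == pytest.approx(0.04)

    def test_drive_saturates_at_ceiling(self):
        sgc = CyclaseSource("cGMP", j_basal=0.01, max_stim_factor=6.0, no_input=1.0)
        assert synthesis_rate(sgc, TreatmentEffects(reduced_sgc_drive=100.0)) == pytest.approx(0.06)


class TestExchange:
    def test_equilibrium_and_decoupled(self):
        assert exchange_flux(1.5, 1.5, 0.3) == 0.0
        assert exchange_flux(2.0, 1.0, 0.0) == 0.0

    def test_first_order_arithmetic(self):
        assert exchange_flux(2.0, 1.0, 0.1) == pytest.approx(0.1)

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(InvalidInputError):
            exchange_flux(1.0, 1.0, -0.1)

    def test_mass_conserved_along_trajectory(self, two_compartment_model, rng):
        # synthesis and hydrolysis off: total mass sum(V_i S_i) is invariant
        model = two_compartment_model
        stripped = CellModel(
            genotype="control", nucleotide="cAMP",
            compartments=tuple(
                Compartment(c.name, c.volume_fraction, (), (), dict(c.exchanges))
                for c in model.compartments))
        s0 = rng.uniform(0.5, 3.0, size=2)
        grid = np.linspace(0, 50, 26)
        conc = simulate_schedule(stripped, [(0.0, 50.0, UNTREATED)], grid, s0=s0)
        vols = np.array([c.volume_fraction for c in stripped.compartments])
        mass = conc @ vols
        assert np.allclose(mass, mass[0], rtol=1e-7)


class TestAssembleRhs:
    def test_all_zero_rates(self):
        comp = Compartment("CYT", 1.0)
        model = CellModel("control", "cAMP", (comp,))
        assert assemble_rhs(model, [1.0]) == pytest.approx([0.0])

    def test_balanced_single_compartment(self, one_compartment_model):
        # J = Vmax/2 and S = Km: hydrolysis exactly balances synthesis
        assert assemble_rhs(one_compartment_model, [5.0])[0] == pytest.approx(0.0, abs=1e-15)

    def test_two_compartment_hand_assembled(self, two_compartment_model):
        model = two_compartment_model
        s = np.array([2.0, 0.5])
        rhs = assemble_rhs(model, s)
        pde8 = model.compartment("OMM").pdes[0][0]
        hydro = michaelis_menten_rate(pde8, 0.5)
        expect_omm = 0.5 * (2.0 - 0.5) - hydro
        expect_cyt = 0.004 - 0.5 * (2.0 - 0.5) * (0.1 / 0.9)
        assert rhs[1] == pytest.approx(expect_omm, rel=1e-12)
        assert rhs[0] == pytest.approx(expect_cyt, rel=1e-12)

    def test_dimension_mismatch(self, one_compartment_model):
        with pytest.raises(StructuralError):
            assemble_rhs(one_compartment_model, [1.0, 2.0])


class TestSteadyState:
    def test_closed_form_single_pde(self, one_compartment_model):
        # S* = J Km / (Vmax - J); here J = Vmax/2 so S* = Km = 5
        s = solve_steady_state(one_compartment_model)
        assert s[0] == pytest.approx(5.0, rel=1e-8)

    def test_no_steady_state_at_capacity(self):
        pde4 = pde_isoform("PDE4")
        comp = Compartment("CYT", 1.0, pdes=((pde4, 1.0),),
                           cyclases=(CyclaseSource("cAMP", j_basal=0.03,
                                                   max_stim_factor=4.0),))
        model = CellModel("control", "cAMP", (comp,))
        with pytest.raises(NoSteadyStateError):
            solve_steady_state(model)

    def test_random_one_compartment_against_closed_form(self, rng):
        for _ in range(100):
            km = float(rng.uniform(0.05, 20.0))
            vmax = float(rng.uniform(0.01, 0.5))
            j = float(rng.uniform(0.05, 0.95)) * vmax
            iso = pde_isoform("PDE4", density_factor=1.0)
            iso = type(iso)(name="PDE4", substrate="cAMP", km_uM={"cAMP": km},
                            vmax_specific=vmax, density_factor=1.0)
            comp = Compartment("CYT", 1.0, pdes=((iso, 1.0),),
                               cyclases=(CyclaseSource("cAMP", j_basal=j,
                                                       max_stim_factor=4.0),))
            model = CellModel("control", "cAMP", (comp,))
            expect = j * km / (vmax - j)
            assert solve_steady_state(model)[0] == pytest.approx(expect, rel=1e-6)

    def test_two_compartment_against_algebraic_oracle(self, rng):
        # independent oracle: OMM balance gives v8(S_o) = J * Vc/Vo, solved in
        # closed form; CYT then follows from the exchange balance.
        for _ in range(50):
            vc, vo = 0.9, 0.1
            km = float(rng.uniform(0.05, 5.0))
            vmax = float(rng.uniform(0.05, 0.5))
            k_ex = float(rng.uniform(0.05, 2.0))
            a = float(rng.uniform(0.1, 0.9)) * vmax  # required OMM hydrolysis
            j = a * vo / vc
            iso = type(pde_isoform("PDE8"))(name="PDE8", substrate="cAMP",
                                            km_uM={"cAMP": km}, vmax_specific=vmax,
                                            density_factor=1.0)
            cyt = Compartment("CYT", vc,
                              cyclases=(CyclaseSource("cAMP", j_basal=j,
                                                      max_stim_factor=4.0),))
            omm = Compartment("OMM", vo, pdes=((iso, 1.0),), exchanges={"CYT": k_ex})
            model = CellModel("control", "cAMP", (cyt, omm))
            s_omm = a * km / (vmax - a)
            s_cyt = s_omm + a / k_ex
            s = solve_steady_state(model)
            assert s[0] == pytest.approx(s_cyt, rel=1e-6)
            assert s[1] == pytest.approx(s_omm, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(dose_scale=st.floats(0.0, 1.0), stim=st.floats(0.0, 1.0))
    def test_monotone_in_inhibition_and_stimulation(self, dose_scale, stim):
        pde4 = pde_isoform("PDE4")
        comp = Compartment("CYT", 1.0, pdes=((pde4, 1.0),),
                           cyclases=(CyclaseSource("cAMP", j_basal=0.005,
                                                   max_stim_factor=2.0),))
        model = CellModel("control", "cAMP", (comp,))
        base = solve_steady_state(model)[0]
        s_inh = solve_steady_state(model, TreatmentEffects(
            inhibition={"PDE4": 0.5 * dose_scale}))[0]
        s_stim = solve_steady_state(model, TreatmentEffects(ac_drive=stim))[0]
        assert s_inh >= base - 1e-9
        assert s_stim >= base - 1e-9


class TestSimulateSchedule:
    def test_flat_at_steady_state(self, one_compartment_model):
        grid = np.arange(0.0, 200.0, 10.0)
        conc = simulate_schedule(one_compartment_model, [(0.0, 200.0, UNTREATED)], grid)
        assert np.allclose(conc[:, 0], conc[0, 0], rtol=1e-7)

    def test_step_rise_is_monotone_without_overshoot(self):
        # first-order system: monotone approach to the new steady state
        pde4 = pde_isoform("PDE4")
        comp = Compartment("CYT", 1.0, pdes=((pde4, 1.0),),
                           cyclases=(CyclaseSource("cAMP", j_basal=0.006,
                                                   max_stim_factor=2.0),))
        model = CellModel("control", "cAMP", (comp,))
        stim = TreatmentEffects(ac_drive=0.5)
        grid = np.arange(0.0, 4000.0, 10.0)
        schedule = [(0.0, 300.0, UNTREATED), (300.0, 4000.0, stim)]
        conc = simulate_schedule(model, schedule, grid)[:, 0]
        target = solve_steady_state(model, stim)[0]
        post = conc[30:]
        assert np.all(np.diff(post) > -1e-9)
        assert np.max(post) <= target + 1e-6
        assert post[-1] == pytest.approx(target, rel=1e-3)

    def test_step_matches_tight_tolerance_reference(self, one_compartment_model):
        model = one_compartment_model
        stim = TreatmentEffects(ac_drive=0.5)
        grid = np.arange(0.0, 900.0, 10.0)
        schedule = [(0.0, 300.0, UNTREATED), (300.0, 900.0, stim)]
        loose = simulate_schedule(model, schedule, grid, rtol=1e-8, atol=1e-10)
        tight = simulate_schedule(model, schedule, grid, rtol=1e-10, atol=1e-12)
        assert np.allclose(loose, tight, rtol=1e-6)

    def test_full_block_grows_without_bound(self, one_compartment_model):
        model = one_compartment_model
        ibmx = TreatmentEffects(inhibition={"PDE4": 1.0})
        grid = np.arange(0.0, 600.0, 10.0)
        schedule = [(0.0, 100.0, UNTREATED), (100.0, 600.0, ibmx)]
        conc = simulate_schedule(model, schedule, grid)[:, 0]
        assert np.all(np.diff(conc[11:]) > 0)
        # zero-order synthesis: asymptotically linear growth at J
        assert conc[-1] - conc[-2] == pytest.approx(0.015 * 10.0, rel=1e-3)


class TestModelValidation:
    def test_double_sided_exchange_rejected(self):
        a = Compartment("CYT", 0.5, exchanges={"PM": 0.1})
        b = Compartment("PM", 0.5, exchanges={"CYT": 0.1})
        with pytest.raises(StructuralError):
            CellModel("control", "cAMP", (a, b))

    def test_disconnected_graph_rejected(self):
        a = Compartment("CYT", 0.5)
        b = Compartment("PM", 0.4)
        with pytest.raises(StructuralError):
            CellModel("control", "cAMP", (a, b))

    def test_volume_fractions_bounded(self):
        with pytest.raises(InvalidInputError):
            Compartment("CYT", 0.0)
        a = Compartment("CYT", 0.8, exchanges={"PM": 0.1})
        b = Compartment("PM", 0.4)
        with pytest.raises(InvalidInputError):
            CellModel("control", "cAMP", (a, b))
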