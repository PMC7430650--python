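"""Unit and property tests for scheme declaration and mass-action simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ires40s.reaction_model import (
    ExperimentDesign,
    RateConstants,
    build_scheme,
    conservation_error,
    equilibrium_state,
    simulate,
    simulate_chase,
    simulate_states,
)


def fixed_point_equilibrium(rates, a_tot, i_tot, iters=20000, mix=0.02):
    """Independent oracle: damped fixed-point iteration of the coupled
    step-1 and step-2 equilibria under 40S and IRES conservation."""
    f = rates.K_half / (1 + rates.K_half)
    a_act = f * a_tot
    kd1, k2 = rates.k_neg1 / rates.k1, rates.k2 / rates.k_neg2
    c1 = c2 = 0.0
    for _ in range(iters):
        a_free = a_act - c1 - c2
        i_free = i_tot - c1 - c2
        c1_new = a_free * i_free / kd1
        c2_new = k2 * c1_new
        c1 += mix * (c1_new - c1)
        c2 += mix * (c2_new - c2)
    return c1, c2


class TestBuildScheme:
    def test_two_step_topology(self, wt):
        scheme = build_scheme("two_step_reversible", wt)
        assert len(scheme.species) == 5
        assert len(scheme.reactions) == 4  # two reversible steps
        symbols = {r.rate_symbol for r in scheme.reactions}
        assert symbols == {"k1", "k_neg1", "k2", "k_neg2"}

    def test_one_step_topology(self, wt):
        scheme = build_scheme("one_step_reversible", wt)
        assert "C2" not in scheme.species
        assert len(scheme.reactions) == 2

    def test_reactions_conserve_molecules(self, wt):
        for sid in ("two_step_reversible", "one_step_reversible",
                    "parallel_reversible", "two_populations"):
            scheme = build_scheme(sid, wt)
            s40, sir = set(scheme.species_40S), set(scheme.species_ires)
            for rxn in scheme.reactions:
                n40 = sum(s in s40 for s in rxn.reactants) - sum(
                    s in s40 for s in rxn.products)
                nir = sum(s in sir for s in rxn.reactants) - sum(
                    s in sir for s in rxn.products)
                assert n40 == 0 and nir == 0

    def test_unknown_scheme_raises(self, wt):
        with pytest.raises(ValueError, match="unknown scheme_id"):
            build_scheme("three_step_magic", wt)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="must be finite and >= 0"):
            RateConstants(k1=-1.0, k_neg1=1.0, k2=1.0, k_neg2=1.0, K_half=1.0)

    def test_zero_rates_simulate_to_constant_state(self):
        rates = RateConstants(0.0, 0.0, 0.0, 0.0, 1.0)
        scheme = build_scheme("two_step_reversible", rates)
        design = ExperimentDesign("association", 1.0, 4.0, (0.5, 1.0, 5.0))
        tc = simulate(scheme, design)
        assert np.allclose(tc.frac_bound, 0.0)


class TestSimulate:
    def test_no_preformed_complex_at_time_zero(self, wt):
        scheme = build_scheme("two_step_reversible", wt)
        design = ExperimentDesign("association", 1.0, 4.0, (0.0, 1.0))
        tc = simulate(scheme, design)
        assert tc.frac_bound[0] == 0.0

    def test_no_association_flux_means_no_binding(self, wt):
        rates = RateConstants(0.0, wt.k_neg1, wt.k2, wt.k_neg2, wt.K_half)
        scheme = build_scheme("two_step_reversible", rates)
        design = ExperimentDesign("association", 1.0, 4.0, (0.5, 2.0, 10.0))
        assert np.allclose(simulate(scheme, design).frac_bound, 0.0)

    def test_plateau_matches_algebraic_equilibrium(self, wt):
        # long-time ODE plateau vs the quadratic with Kd_eff = Kd1/(1+K2)
        scheme = build_scheme("two_step_reversible", wt)
        design = ExperimentDesign("association", 1.0, 4.0, (2000.0,))
        plateau = simulate(scheme, design).frac_bound[-1]
        eq = equilibrium_state(wt, 1.0, 4.0)
        assert plateau == pytest.approx((eq["C1"] + eq["C2"]) / 4.0, rel=1e-5)
        assert plateau == pytest.approx(0.2309, abs=2e-4)  # frozen oracle value

    def test_association_monotone_before_plateau(self, wt, design_suite):
        scheme = build_scheme("two_step_reversible", wt)
        for d in design_suite:
            if d.mode != "association":
                continue
            tc = simulate(scheme, d)
            assert np.all(np.diff(tc.frac_bound) > -1e-10)

    def test_partition_fraction_exact_at_t0(self, wt):
        scheme = build_scheme("two_step_reversible", wt)
        y0 = scheme.initial_concentrations(1.0, 4.0)
        idx = {s: i for i, s in enumerate(scheme.species)}
        active = y0[idx["40S_A"]]
        total = active + y0[idx["40S_in"]]
        assert active / total == wt.K_half / (1 + wt.K_half)

    def test_detailed_balance_limit_reduces_to_one_step(self, wt):
        # k2 = k-2 = 0: the two-step plateau equals the one-step plateau
        frozen = RateConstants(wt.k1, wt.k_neg1, 0.0, 0.0, wt.K_half)
        design = ExperimentDesign("association", 1.0, 2.5, (500.0,))
        two = simulate(build_scheme("two_step_reversible", frozen), design)
        one = simulate(build_scheme("one_step_reversible", frozen), design)
        assert two.frac_bound[-1] == pytest.approx(one.frac_bound[-1], rel=1e-6)

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ExperimentDesign("association", 1.0, 4.0, (1.0, 1.0, 2.0))


class TestChase:
    def test_chase_decay_is_non_increasing(self, wt, design_suite):
        scheme = build_scheme("two_step_reversible", wt)
        chase = [d for d in design_suite if d.mode == "chase"][0]
        tc = simulate_chase(scheme, chase)
        assert np.all(np.diff(tc.frac_bound) <= 1e-12)

    def test_no_dissociation_flux_means_constant_signal(self, wt, design_suite):
        rates = RateConstants(wt.k1, 0.0, wt.k2, 0.0, wt.K_half)
        scheme = build_scheme("two_step_reversible", rates)
        chase = [d for d in design_suite if d.mode == "chase"][0]
        tc = simulate_chase(scheme, chase)
        assert np.allclose(tc.frac_bound, tc.frac_bound[0], rtol=1e-9)

    def test_explicit_competitor_close_to_flux_zeroing(self, wt, design_suite):
        # 450-fold competitor excess: explicit cold species give nearly the
        # same decay as suppressing labeled re-association outright
        scheme = build_scheme("two_step_reversible", wt)
        chase = [d for d in design_suite if d.mode == "chase"][0]
        fz = simulate_chase(scheme, chase, competitor="flux_zero")
        ex = simulate_chase(scheme, chase, competitor="explicit")
        assert np.max(np.abs(fz.frac_bound - ex.frac_bound)) < 5e-3

    def test_preincubation_required(self, wt):
        with pytest.raises(ValueError, match="preincubation"):
            ExperimentDesign("chase", 2.0, 2.0, (1.0, 5.0),
                             preincubation=None, conc_competitor=900.0)


class TestEquilibriumState:
    def test_complex_ratio_equals_step2_equilibrium_constant(self, wt):
        eq = equilibrium_state(wt, 1.0, 4.0)
        assert eq["C2"] / eq["C1"] == pytest.approx(18.0, rel=1e-12)

    def test_no_ires_no_complex(self, wt):
        eq = equilibrium_state(wt, 1.0, 0.0)
        assert eq["C1"] == 0.0 and eq["C2"] == 0.0

    def test_matches_fixed_point_oracle(self, wt):
        c1, c2 = fixed_point_equilibrium(wt, 2.0, 2.0)
        eq = equilibrium_state(wt, 2.0, 2.0)
        assert eq["C1"] == pytest.approx(c1, rel=1e-6)
        assert eq["C2"] == pytest.approx(c2, rel=1e-6)
        # effective Kd check: Kd1/(1+K2) = 4.2/19
        assert wt.Kd1 / (1 + wt.K2) == pytest.approx(0.2211, abs=1e-4)

    def test_requires_binding(self, wt):
        with pytest.raises(ValueError, match="k1"):
            equilibrium_state(
                RateConstants(0.0, 1.0, 1.0, 1.0, 1.0), 1.0, 1.0)


class TestConservationAndPlateaus:
    def test_conservation_along_trajectories(self, wt, design_suite):
        scheme = build_scheme("two_step_reversible", wt)
        for d in design_suite:
            if d.mode != "association":
                continue
            states = simulate_states(scheme, d)
            err = conservation_error(scheme, states, d.conc_40S_total,
                                     d.conc_IRES_labeled)
            assert err < 1e-7

    @given(
        k1=st.floats(0.05, 5.0), k_neg1=st.floats(0.5, 20.0),
        k2=st.floats(0.02, 1.0), k_neg2=st.floats(0.005, 0.5),
        K_half=st.floats(0.2, 99.0),
    )
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_random_rates_conserve_and_stay_in_range(self, k1, k_neg1, k2,
                                                     k_neg2, K_half):
        rates = RateConstants(k1, k_neg1, k2, k_neg2, K_half)
        scheme = build_scheme("two_step_reversible", rates)
        design = ExperimentDesign("association", 1.0, 2.5,
                                  (0.25, 1.0, 5.0, 30.0))
        states = simulate_states(scheme, design)
        assert conservation_error(scheme, states, 1.0, 2.5) < 1e-6
        frac = simulate(scheme, design).frac_bound
        assert np.all(frac >= -1e-9) and np.all(frac <= 1 + 1e-9)

    def test_interconversion_preserves_partition_ratio(self, wt):
        # slow explicit 40S_in <-> 40S_A exchange must not shift a system
        # started at its partition equilibrium
        scheme = build_scheme("two_step_reversible", wt, interconversion_rate=0.05)
        rates0 = RateConstants(0.0, 0.0, 0.0, 0.0, wt.K_half)
        idle = build_scheme("two_step_reversible", rates0, interconversion_rate=0.05)
        design = ExperimentDesign("association", 1.0, 1.0, (50.0,))
        states = simulate_states(idle, design)
        conc = states[-1].concentrations
        ratio = conc["40S_A"] / (conc["40S_A"] + conc["40S_in"])
        assert ratio == pytest.approx(wt.K_half / (1 + wt.K_half), rel=1e-6)
        # and with binding switched on the trajectory still conserves mass
        st2 = simulate_states(scheme, design)
        assert conservation_error(scheme, st2, 1.0, 1.0) < 1e-7
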