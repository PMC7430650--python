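"""Tests for biphasic pre-fits, global fitting, profiles and model ranking."""

import numpy as np
import pytest

from ires40s.estimation import (
    compare_models,
    fit_biphasic,
    global_fit,
    initial_parameters,
    profile_confidence,
)
from ires40s import units
from ires40s.estimation import fit_pipeline
from ires40s.reaction_model import (
    ExperimentDesign,
    RateConstants,
    TimeCourse,
    build_scheme,
    simulate_chase,
    simulate_states,
)
from ires40s.synthetic_data import NoiseModel, generate_dataset


def _tc(times, values, design=None):
    design = design or ExperimentDesign(
        "association", 1.0, 4.0, tuple(times), experiment_id="synthetic")
    return TimeCourse(design=design, times=np.asarray(times),
                      frac_bound=np.asarray(values))


class TestBiphasicFit:
    def test_recovers_known_biphasic_parameters(self):
        t = np.linspace(0.01, 60, 20)
        y = 0.5 * np.exp(-3 * t) + 0.3 * np.exp(-0.1 * t) + 0.2
        fit = fit_biphasic(_tc(t, y))
        assert fit.a1 == pytest.approx(0.5, rel=1e-4)
        assert fit.b1 == pytest.approx(3.0, rel=1e-4)
        assert fit.a2 == pytest.approx(0.3, rel=1e-4)
        assert fit.b2 == pytest.approx(0.1, rel=1e-4)
        assert fit.c == pytest.approx(0.2, rel=1e-4)
        assert fit.b1 >= fit.b2

    def test_single_exponential_nested_limit(self):
        t = np.linspace(0.1, 30, 15)
        y = 0.4 * np.exp(-0.5 * t) + 0.1
        fit = fit_biphasic(_tc(t, y))
        assert fit.rss < 1e-10
        # one amplitude vanishes or the two rates coincide
        assert min(abs(fit.a1), abs(fit.a2)) < 1e-3 or \
            fit.b1 == pytest.approx(fit.b2, rel=1e-2)

    def test_constant_data(self):
        t = np.linspace(0, 10, 8)
        fit = fit_biphasic(_tc(t, np.full_like(t, 0.33)))
        assert abs(fit.a1) < 1e-6 and abs(fit.a2) < 1e-6
        assert fit.c == pytest.approx(0.33, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 6 points"):
            fit_biphasic(_tc([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.35, 0.4]))


class TestInitialParameters:
    def test_assignment_rules(self):
        assoc = [fit_biphasic(_tc(np.linspace(0.1, 10, 12),
                                  -0.3 * np.exp(-5 * t_) - 0.2 * np.exp(-0.18 * t_) + 0.5))
                 for t_ in [np.linspace(0.1, 10, 12)]]
        chase_t = np.geomspace(0.02, 60, 25)
        chase = fit_biphasic(_tc(chase_t,
                                 0.1 * np.exp(-5.4 * chase_t)
                                 + 0.5 * np.exp(-0.01 * chase_t)))
        init = initial_parameters(assoc, chase)
        assert init.k2 == pytest.approx(assoc[0].b2, rel=1e-9)
        assert init.k_neg1 == pytest.approx(5.4, rel=1e-3)
        assert init.k_neg2 == pytest.approx(0.01, rel=1e-3)

    def test_k1_start_below_cap(self):
        t = np.linspace(0.1, 10, 10)
        f = fit_biphasic(_tc(t, 0.2 * np.exp(-2 * t) + 0.3 * np.exp(-0.1 * t)))
        init = initial_parameters([f], f)
        assert units.second_order_per_uM_s(init.k1) < 1000.0

    def test_missing_chase_fit_is_an_error(self):
        t = np.linspace(0.1, 10, 10)
        f = fit_biphasic(_tc(t, 0.2 * np.exp(-2 * t) + 0.3 * np.exp(-0.1 * t)))
        with pytest.raises(ValueError, match="chase"):
            initial_parameters([f], None)


class TestGlobalFit:
    def test_one_step_self_consistency(self, design_suite):
        truth = RateConstants(1.0, 3.0, 0.0, 0.0, 9.0)
        # one-step scheme only uses k1, k_neg1, K_half
        data = generate_dataset(truth, design_suite, NoiseModel(0, 1, 0),
                                scheme_id="one_step_reversible")
        init = RateConstants(3.0, 1.0, 0.1, 0.01, 9.0)
        res = global_fit(data, "one_step_reversible", init)
        assert res.converged
        assert res.ssr < 1e-8
        assert res.params["k1"] == pytest.approx(1.0, rel=1e-2)
        assert res.params["k_neg1"] == pytest.approx(3.0, rel=1e-2)

    def test_chi2_equals_recomputed_weighted_ssr(self, wt_fit, wt_noiseless):
        # recompute the weighted SSR independently from stored residuals
        recomputed = sum(float(np.sum(r**2)) for r in wt_fit.residuals)
        assert wt_fit.chi2 == pytest.approx(recomputed, rel=1e-12)
        assert wt_fit.n_points == sum(len(tc) for tc in wt_noiseless)

    def test_noiseless_wt_recovery_within_one_percent(self, wt, wt_fit):
        for name, truth in wt.as_dict().items():
            if name == "K_half":
                continue  # nearly saturated partition: checked via Kd1 below
            assert wt_fit.params[name] == pytest.approx(truth, rel=1e-2), name
        assert wt_fit.rates.Kd1 == pytest.approx(wt.Kd1, rel=1e-2)

    @pytest.mark.parametrize("draw", range(10))
    def test_generate_and_refit_random_parameter_sets(self, draw, design_suite):
        rng = np.random.default_rng(1000 + draw)
        truth = RateConstants(
            k1=10 ** rng.uniform(-0.7, 0.7),
            k_neg1=10 ** rng.uniform(0.0, 1.2),
            k2=10 ** rng.uniform(-1.3, -0.3),
            k_neg2=10 ** rng.uniform(-2.2, -1.0),
            K_half=10 ** rng.uniform(0.0, 1.5),
        )
        data = generate_dataset(truth, design_suite, NoiseModel(0, 1, 0))
        start = {k: v * 10 ** rng.uniform(-0.4, 0.4)
                 for k, v in truth.as_dict().items()}
        res = global_fit(data, "two_step_reversible", start)
        assert res.converged
        for name, v in truth.as_dict().items():
            assert res.params[name] == pytest.approx(v, rel=1e-2), name


class TestMechanismLink:
    def test_chase_biphasic_rates_reflect_dissociation_constants(
            self, wt, design_suite):
        # the observed fast/slow chase rates approximate k-1 and k-2
        scheme = build_scheme("two_step_reversible", wt)
        chase = [d for d in design_suite if d.mode == "chase"][0]
        fit = fit_biphasic(simulate_chase(scheme, chase))
        assert fit.b1 == pytest.approx(wt.k_neg1, rel=0.15)
        assert fit.b2 == pytest.approx(wt.k_neg2, rel=0.15)

    def test_fast_phase_amplitude_reflects_complex_partition(
            self, wt, design_suite):
        # amplitude of the fast chase phase ~ C1/(C1+C2) at competitor
        # addition, computed independently from the association ODE
        scheme = build_scheme("two_step_reversible", wt)
        chase = [d for d in design_suite if d.mode == "chase"][0]
        pre = ExperimentDesign("association", chase.conc_40S_total,
                               chase.conc_IRES_labeled, (chase.preincubation,))
        conc = simulate_states(scheme, pre)[-1].concentrations
        c1_share = conc["C1"] / (conc["C1"] + conc["C2"])
        fit = fit_biphasic(simulate_chase(scheme, chase))
        amp_share = fit.a1 / (fit.a1 + fit.a2)
        assert amp_share == pytest.approx(c1_share, rel=0.25)


class TestProfileConfidence:
    def test_bounds_collapse_without_noise(self, design_suite, wt):
        # intervals of the well-identified constants shrink below 1%
        # relative at sigma = 1e-4; k1/k-1 share a sloppy direction with
        # the nearly saturated partition constant and stay an order wider
        data = generate_dataset(wt, design_suite, NoiseModel(1e-4, 1, 5))
        res, _ = fit_pipeline(data, k1_starts=(6.0,))
        cb = profile_confidence(data, res, params=["k1", "k_neg1", "k2", "k_neg2"])
        for name in ("k2", "k_neg2"):
            lo, hi = cb.bounds[name]
            assert (hi - lo) / res.params[name] < 1e-2, name
        for name in ("k1", "k_neg1"):
            lo, hi = cb.bounds[name]
            assert (hi - lo) / res.params[name] < 0.1, name

    def test_truth_inside_bounds_on_noisy_data(self, design_suite, wt):
        data = generate_dataset(wt, design_suite, NoiseModel(0.03, 3, 11))
        res, _ = fit_pipeline(data)
        cb = profile_confidence(data, res)
        assert cb.contains(wt.as_dict())
        for name, (lo, hi) in cb.bounds.items():
            assert lo <= res.params[name] <= hi

    def test_truncated_chase_leaves_k_neg2_unbounded_above(self, wt):
        # without the chase tail the slow back-conversion is unidentified
        from ires40s.synthetic_data import paper_design_suite
        designs = paper_design_suite()
        short = []
        for d in designs:
            if d.mode == "chase":
                tp = tuple(t for t in d.timepoints if t <= 5.0) or (1.0, 3.0, 5.0)
                d = ExperimentDesign("chase", d.conc_40S_total,
                                     d.conc_IRES_labeled,
                                     (0.5, 1.0, 2.0, 3.0, 4.0, 5.0),
                                     preincubation=d.preincubation,
                                     conc_competitor=d.conc_competitor,
                                     experiment_id=d.experiment_id)
            short.append(d)
        data = generate_dataset(wt, short, NoiseModel(0.03, 3, 3))
        res, _ = fit_pipeline(data, k1_starts=(6.0,))
        cb = profile_confidence(data, res, params=["k_neg2"])
        lo, hi = cb.bounds["k_neg2"]
        open_lo, open_hi = cb.open_bounds["k_neg2"]
        assert open_hi or hi / res.params["k_neg2"] > 50.0

    def test_bound_widths_grow_with_noise(self, design_suite, wt):
        widths = []
        for sigma in (0.01, 0.03, 0.06):
            data = generate_dataset(wt, design_suite, NoiseModel(sigma, 3, 17))
            res, _ = fit_pipeline(data, k1_starts=(6.0,))
            cb = profile_confidence(data, res, params=["k2"])
            lo, hi = cb.bounds["k2"]
            widths.append(np.log(hi / lo))
        assert widths[0] < widths[1] < widths[2]


class TestCompareModels:
    def test_true_one_step_model_wins_on_its_own_data(self, design_suite):
        truth = RateConstants(1.0, 3.0, 0.0, 0.0, 9.0)
        data = generate_dataset(truth, design_suite, NoiseModel(0, 1, 0),
                                scheme_id="one_step_reversible")
        init = RateConstants(2.0, 1.0, 0.1, 0.01, 9.0)
        mc = compare_models(data, ["one_step_reversible", "two_step_reversible"],
                            init)
        assert mc.best == "one_step_reversible"

    def test_identical_schemes_tie_break_by_declaration_order(
            self, wt, wt_noiseless):
        mc = compare_models(wt_noiseless,
                            ["two_step_reversible", "two_step_reversible"], wt)
        rows = sorted(mc.table, key=lambda r: r["rank"])
        assert rows[0]["chi2"] == pytest.approx(rows[1]["chi2"], rel=1e-6)

    def test_requires_two_schemes(self, wt, wt_noiseless):
        with pytest.raises(ValueError, match="two schemes"):
            compare_models(wt_noiseless, ["two_step_reversible"], wt)
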