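import numpy as np
import pytest
from scipy.integrate import quad

from petflux.aif import eval_aif, frame_average_aif
from petflux.frames import Curve, compute_weights
from petflux.kinetics import (
    fit_compartment,
    fit_spline_residue,
    flux_constant,
    flux_constant_closed_form,
    model_tac,
    patlak_fit,
    residue_function,
    static_measures,
)
from petflux.simulate import DEFAULT_AIF, simulate_tac


def _random_params(model_id, rng):
    p = {
        "K1": rng.uniform(0.02, 0.5),
        "k2": rng.uniform(0.01, 1.0),
        "k3": rng.uniform(0.01, 0.5),
        "Vb": rng.uniform(0.0, 0.3),
    }
    if model_id in ("2C4K", "3C5K"):
        p["k4"] = rng.uniform(0.0, 0.2)
    if model_id == "3C5K":
        p["k5"] = rng.uniform(0.01, 0.2)
    return p


class TestResidueFunction:
    def test_no_efflux_no_transfer_traps_everything(self):
        r = residue_function("2C3K", {"K1": 0.1, "k2": 0.0, "k3": 0.0},
                             np.array([0.0, 5.0, 100.0]))
        assert r == pytest.approx([1.0, 1.0, 1.0])

    def test_pure_washout_is_single_exponential(self):
        t = np.linspace(0.0, 20.0, 7)
        r = residue_function("2C3K", {"K1": 0.2, "k2": 0.4, "k3": 0.0}, t)
        assert r == pytest.approx(np.exp(-0.4 * t), rel=1e-10)

    def test_trapped_fraction_limit(self):
        r_inf = residue_function("2C3K", {"K1": 0.1, "k2": 0.3, "k3": 0.1},
                                 np.array([1e6]))[0]
        assert r_inf == pytest.approx(0.25, rel=1e-9)

    def test_starts_at_one_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0.0, 100.0, 300)
        for model in ("2C3K", "2C4K", "3C5K"):
            for _ in range(20):
                p = _random_params(model, rng)
                r = residue_function(model, p, t)
                assert r[0] == pytest.approx(1.0, abs=1e-9)
                assert np.all(r <= 1.0 + 1e-9) and np.all(r >= -1e-9)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            residue_function("2C3K", {"K1": 0.1, "k2": -0.1, "k3": 0.0},
                             np.array([1.0]))


class TestFluxConstant:
    def test_2c3k_formula(self):
        p = {"K1": 0.1, "k2": 0.3, "k3": 0.1}
        assert flux_constant_closed_form("2C3K", p) == pytest.approx(0.025)

    def test_no_efflux_limit_is_k1(self):
        p = {"K1": 0.37, "k2": 0.0, "k3": 0.2}
        assert flux_constant_closed_form("2C3K", p) == pytest.approx(0.37)

    @pytest.mark.parametrize("model", ["2C3K", "3C5K"])
    def test_closed_form_equals_k1_times_late_residue(self, model):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = _random_params(model, rng)
            cf = flux_constant_closed_form(model, p)
            late = p["K1"] * residue_function(model, p, np.array([1e4]))[0]
            assert cf == pytest.approx(late, rel=1e-6, abs=1e-12)


class TestModelTac:
    def test_zero_influx_reduces_to_blood_term(self, schedule):
        p = {"K1": 0.0, "k2": 0.3, "k3": 0.1, "Vb": 0.07}
        tac = model_tac("2C3K", p, DEFAULT_AIF, schedule)
        blood = 0.07 * frame_average_aif(DEFAULT_AIF, schedule)
        assert tac.values == pytest.approx(blood, rel=1e-12)

    def test_reversible_tissue_washes_out(self, schedule):
        # k3 = 0: after the input decays away, the tissue term empties
        p = {"K1": 0.2, "k2": 0.5, "k3": 0.0, "Vb": 0.0}
        from petflux.kinetics import tissue_response

        resp = tissue_response("2C3K", p, DEFAULT_AIF)
        assert resp(np.array([2000.0]))[0] == pytest.approx(0.0, abs=1e-6)

    def test_analytic_convolution_matches_quadrature(self, schedule):
        rng = np.random.default_rng(7)
        f = lambda x: eval_aif(DEFAULT_AIF, np.array([x]))[0]
        for model in ("2C3K", "2C4K"):
            p = _random_params(model, rng)
            tac = model_tac(model, p, DEFAULT_AIF, schedule)

            def pointwise(tt):
                r = lambda u: residue_function(model, p, np.array([u]))[0]
                conv = quad(lambda s: f(s) * r(tt - s), 0.0, tt, limit=400)[0]
                return p["K1"] * conv + p["Vb"] * f(tt)

            for i in (10, 30, 38):
                a = max(schedule.start_times_min[i], 0.0)
                b = schedule.end_times_min[i]
                num = quad(pointwise, a, b, limit=100)[0] / (
                    schedule.end_times_min[i] - schedule.start_times_min[i]
                )
                assert tac.values[i] == pytest.approx(num, rel=1e-6)


class TestFitCompartment:
    def test_noiseless_recovery_within_1pct(
        self, schedule, aif_params, params_2c3k, noiseless_tac, tac_weights
    ):
        fit = fit_compartment("2C3K", noiseless_tac, aif_params, schedule,
                              tac_weights)
        for name, true in params_2c3k.items():
            assert fit.params[name] == pytest.approx(true, rel=0.01)
        assert fit.k_flux == pytest.approx(
            flux_constant_closed_form("2C3K", params_2c3k), rel=0.01
        )

    def test_nested_model_never_fits_worse(
        self, schedule, aif_params, noiseless_tac
    ):
        tac = simulate_tac("2C3K", {"K1": 0.15, "k2": 0.35, "k3": 0.08,
                                    "Vb": 0.06},
                           aif_params, schedule, seed=4, noise_scale=1.0)
        w = compute_weights(schedule, tac.values)
        f3 = fit_compartment("2C3K", tac, aif_params, schedule, w, seed=0)
        f4 = fit_compartment("2C4K", tac, aif_params, schedule, w, seed=0,
                             x0=np.array([f3.params["K1"], f3.params["k2"],
                                          f3.params["k3"], 0.0,
                                          f3.params["Vb"]]))
        assert f4.wrss <= f3.wrss * (1.0 + 1e-9)

    def test_scale_equivariance(self, schedule, aif_params, params_2c3k,
                                noiseless_tac, tac_weights):
        # common rescaling of AIF and TAC leaves rate constants unchanged
        c = 10.0
        from petflux.aif import AifParams

        aif10 = AifParams(
            tau=aif_params.tau, A1=c * aif_params.A1, A2=c * aif_params.A2,
            A3=c * aif_params.A3, mu1=aif_params.mu1, mu2=aif_params.mu2,
            mu3=aif_params.mu3,
        )
        tac10 = Curve(schedule=schedule, values=c * noiseless_tac.values)
        w10 = compute_weights(schedule, tac10.values)
        fit = fit_compartment("2C3K", tac10, aif10, schedule, w10)
        for name, true in params_2c3k.items():
            assert fit.params[name] == pytest.approx(true, rel=0.01)


class TestPatlak:
    def test_exact_linear_coordinates(self, schedule):
        # synthesise a TAC that is exactly linear in Patlak coordinates
        slope, intercept = 0.03, 0.4
        f = DEFAULT_AIF.as_expsum()
        mids = np.maximum(schedule.mid_times_min, 0.0)
        aif_mid = eval_aif(DEFAULT_AIF, mids)
        cum = f.cumulative(mids)
        tac_vals = slope * cum + intercept * aif_mid
        fit = patlak_fit(Curve(schedule=schedule, values=tac_vals),
                         DEFAULT_AIF, schedule, t_star=10.0)
        assert fit.params["K"] == pytest.approx(slope, rel=1e-9)
        assert fit.params["V"] == pytest.approx(intercept, rel=1e-9)
        assert fit.wrss == pytest.approx(0.0, abs=1e-15)

    def test_recovers_2c3k_flux_within_2pct(self, schedule):
        p = {"K1": 0.1, "k2": 0.3, "k3": 0.1, "Vb": 0.0}
        tac = model_tac("2C3K", p, DEFAULT_AIF, schedule)
        fit = patlak_fit(tac, DEFAULT_AIF, schedule, t_star=10.0)
        assert fit.k_flux == pytest.approx(0.025, rel=0.02)

    def test_reversibility_bends_the_plot(self, schedule):
        p = {"K1": 0.12, "k2": 0.3, "k3": 0.08, "k4": 0.03, "Vb": 0.05}
        tac = model_tac("2C4K", p, DEFAULT_AIF, schedule)
        ks = [patlak_fit(tac, DEFAULT_AIF, schedule, t_star=t).k_flux
              for t in (10.0, 15.0, 20.0, 25.0)]
        assert np.all(np.diff(ks) < 0)

    def test_insufficient_late_frames(self, schedule, noiseless_tac):
        with pytest.raises(ValueError, match="t_star"):
            patlak_fit(noiseless_tac, DEFAULT_AIF, schedule, t_star=44.0)


class TestSplineResidue:
    def test_recovers_flux_within_5pct_noiseless(
        self, schedule, aif_params, params_2c3k, noiseless_tac, tac_weights
    ):
        fit = fit_spline_residue(noiseless_tac, aif_params, schedule,
                                 tac_weights)
        true = flux_constant_closed_form("2C3K", params_2c3k)
        assert fit.k_flux == pytest.approx(true, rel=0.05)
        assert fit.k_flux == pytest.approx(
            flux_constant(fit, schedule), rel=1e-9
        )

    def test_residue_constraints_hold(self, schedule, aif_params,
                                      noiseless_tac, tac_weights):
        fit = fit_spline_residue(noiseless_tac, aif_params, schedule,
                                 tac_weights)
        t = np.linspace(0.0, schedule.t_scan_min, 400)
        r = fit.residue(t)
        assert r[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(r) <= 1e-9)
        assert np.all(r >= -1e-12)

    def test_nested_knot_refinement_never_fits_worse(
        self, schedule, aif_params, tac_weights
    ):
        tac = simulate_tac("2C3K", {"K1": 0.15, "k2": 0.35, "k3": 0.08,
                                    "Vb": 0.06},
                           aif_params, schedule, seed=9, noise_scale=1.0)
        w = compute_weights(schedule, tac.values)
        coarse = np.array([1.0, 4.0, 16.0])
        fine = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 30.0])
        f_coarse = fit_spline_residue(tac, aif_params, schedule, w,
                                      interior_knots=coarse)
        f_fine = fit_spline_residue(tac, aif_params, schedule, w,
                                    interior_knots=fine)
        assert f_fine.wrss <= f_coarse.wrss * (1.0 + 1e-9)


class TestStaticMeasures:
    def test_unit_normalisation(self):
        sm = static_measures(2.0, 2.0, 1.0, injected_dose=140.0,
                             body_weight=70.0)
        assert sm.suv_max == pytest.approx(1.0)

    def test_tbr_invariant_under_common_rescaling(self):
        a = static_measures(10.0, 5.0, 2.0, 100.0, 50.0)
        b = static_measures(20.0, 10.0, 4.0, 100.0, 50.0)
        assert b.tbr_max == pytest.approx(a.tbr_max)
        assert b.tbr_mean == pytest.approx(a.tbr_mean)

    def test_worked_example(self):
        sm = static_measures(10.0, 5.0, 2.0, injected_dose=70.0,
                             body_weight=70.0)
        assert sm.suv_max == pytest.approx(10.0)
        assert sm.tbr_mean == pytest.approx(2.5)
        assert sm.tbr_max >= sm.tbr_mean

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            static_measures(1.0, 1.0, 0.0, 1.0, 1.0)
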