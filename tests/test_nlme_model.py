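"""Structural solvers, error models, occasions and fixture handling."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import iovdesign as iv
from iovdesign.nlme_model import (
    DoseEvent,
    DosingRegimen,
    InvalidParameterError,
    solve_colistin,
    solve_onecomp,
)


def simple_regimen(tau=6.0, m=4, dose=1.0):
    events = tuple(DoseEvent(tau * j, dose) for j in range(m))
    return DosingRegimen(events, tau, m, tau * m)


class TestSolveOneComp:
    def test_initial_concentration_is_dose_over_volume(self):
        reg = DosingRegimen((DoseEvent(0.0, 100.0),), 24.0, 1, 24.0)
        c = solve_onecomp(reg, np.array([9.0]), np.array([40.0]), np.array([0.0]))
        assert c[0] == pytest.approx(100.0 / 40.0)

    def test_exponential_decay_single_bolus(self):
        reg = DosingRegimen((DoseEvent(0.0, 1.0),), 24.0, 1, 24.0)
        c = solve_onecomp(reg, np.array([9.0]), np.array([40.0]), np.array([0.0, 6.0]))
        assert c[1] / c[0] == pytest.approx(math.exp(-9.0 * 6.0 / 40.0), rel=1e-12)

    def test_multidose_superposition(self):
        reg = simple_regimen(tau=6.0, m=2, dose=1.0)
        cl, v = np.array([9.0, 9.0]), np.array([40.0, 40.0])
        c = solve_onecomp(reg, cl, v, np.array([7.0]))
        k = 9.0 / 40.0
        expected = (math.exp(-k * 7.0) + math.exp(-k * 1.0)) / 40.0
        assert c[0] == pytest.approx(expected, rel=1e-12)

    def test_amount_continuous_across_occasion_boundary(self):
        # kappa switches elimination at t = 6; amounts must be continuous
        reg = simple_regimen(tau=6.0, m=2, dose=0.0)
        reg = DosingRegimen((DoseEvent(0.0, 1.0),), 6.0, 2, 12.0)
        cl = np.array([9.0, 18.0])
        v = np.array([40.0, 40.0])
        eps = 1e-9
        c = solve_onecomp(reg, cl, v, np.array([6.0 - eps, 6.0]))
        assert c[0] == pytest.approx(c[1], rel=1e-6)

    def test_dose_linearity(self):
        reg1 = DosingRegimen((DoseEvent(0.0, 1.0),), 6.0, 2, 12.0)
        reg2 = DosingRegimen((DoseEvent(0.0, 2.0),), 6.0, 2, 12.0)
        cl, v = np.array([9.0, 12.0]), np.array([40.0, 35.0])
        t = np.linspace(0, 12, 13)
        assert np.allclose(
            2 * solve_onecomp(reg1, cl, v, t), solve_onecomp(reg2, cl, v, t)
        )

    def test_negative_parameter_rejected(self):
        reg = DosingRegimen((DoseEvent(0.0, 1.0),), 6.0, 1, 6.0)
        with pytest.raises(InvalidParameterError):
            solve_onecomp(reg, np.array([-1.0]), np.array([40.0]), np.array([1.0]))


class TestSolveColistin:
    def test_mass_conservation_without_elimination(self, colistin):
        reg = colistin.regimen
        zero = np.zeros(3)
        rates = {"k10": zero, "k12": zero, "k21": zero, "kcol": zero}
        amt = solve_colistin(reg, rates, np.array([0.5, 1.0, 12.2, 36.0]))
        # after the 30-min loading infusion all 413 umol sit in CMS1
        assert amt[0, 0] == pytest.approx(413.0, rel=1e-10)
        assert np.allclose(amt[0, 1:], 0.0)
        # cumulative administered dose at later times
        assert amt[1, 0] == pytest.approx(413.0, rel=1e-10)
        assert amt[2, 0] == pytest.approx(413.0 + 206.5 * 0.2 / 0.5, rel=1e-10)
        assert amt[3, 0] == pytest.approx(413.0 + 2 * 206.5, rel=1e-10)

    def test_matches_adaptive_ode_integration(self, colistin):
        rng = np.random.default_rng(3)
        eta = rng.normal(0, 0.3, 3)
        kap = rng.normal(0, 0.2, (3, 3))
        rates = colistin._rates(eta, kap)
        reg = colistin.regimen

        def rhs(t, x):
            occ = min(int(t // reg.tau), 2)
            rin = sum(
                e.amount / e.duration
                for e in reg.events
                if e.duration > 0 and e.time <= t < e.time + e.duration
            )
            return [
                rin
                - (rates["k12"][occ] + rates["k10"][occ]) * x[0]
                + rates["k21"][occ] * x[1],
                rates["k12"][occ] * x[0] - rates["k21"][occ] * x[1],
                rates["k10"][occ] * x[0] - rates["kcol"][occ] * x[2],
            ]

        ts = np.linspace(0.8, 36.0, 50)
        ode = solve_ivp(
            rhs, (0, 36), [0, 0, 0], t_eval=ts, rtol=1e-12, atol=1e-14, max_step=0.1
        )
        mine = solve_colistin(reg, rates, ts)
        rel = np.abs(mine - ode.y.T) / np.maximum(np.abs(ode.y.T), 1e-8)
        assert np.max(rel) < 1e-8

    def test_dose_linearity(self, colistin):
        reg = colistin.regimen
        reg2 = DosingRegimen(
            tuple(DoseEvent(e.time, 2 * e.amount, e.duration) for e in reg.events),
            reg.tau,
            reg.n_occasions,
            reg.horizon,
        )
        rates = colistin._rates(np.zeros(3), np.zeros((3, 3)))
        t = np.linspace(0.6, 36, 20)
        assert np.allclose(
            2 * solve_colistin(reg, rates, t), solve_colistin(reg2, rates, t)
        )

    def test_amounts_continuous_across_occasion_boundary(self, colistin):
        rng = np.random.default_rng(5)
        kap = rng.normal(0, 0.4, (3, 3))
        rates = colistin._rates(np.zeros(3), kap)
        eps = 1e-9
        amt = solve_colistin(colistin.regimen, rates, np.array([24.0 - eps, 24.0]))
        # dose starts at t=24 (infusion), amounts continuous there
        assert np.allclose(amt[0], amt[1], rtol=1e-6)


class TestModelPredict:
    def test_typical_curve_at_zero_deviations(self, onecomp):
        d = iv.design_from_times(onecomp, [0.0, 3.0])
        pred = iv.model_predict(onecomp, d, onecomp.zero_realization())
        k = 9.0 / 40.0
        assert pred[0] == pytest.approx(500.0 / 40.0)
        assert pred[1] == pytest.approx(500.0 / 40.0 * math.exp(-3 * k))

    def test_eta_cl_doubles_elimination_rate(self, onecomp):
        d = iv.design_from_times(onecomp, [4.0])
        r = iv.IndividualRealization([math.log(2.0), 0.0], np.zeros((4, 2)))
        pred = iv.model_predict(onecomp, d, r)
        base = iv.model_predict(onecomp, d, onecomp.zero_realization())
        assert pred[0] == pytest.approx(
            base[0] * math.exp(-(2 - 1) * 9.0 / 40.0 * 4.0), rel=1e-12
        )

    def test_kappa_fm_halves_colistin_concentration(self, colistin):
        d = iv.Design(np.array([5.0]), np.array([1]), ())
        kap = np.zeros((3, 3))
        kap[0, 2] = math.log(2.0)
        base_amt = colistin.amounts(np.array([5.0]), np.zeros(3), np.zeros((3, 3)))
        amt = colistin.amounts(np.array([5.0]), np.zeros(3), kap)
        # kappa_FM cancels in the elimination rate: amounts unchanged,
        # observed concentration halved through the volume term
        assert np.allclose(base_amt, amt, rtol=1e-10)
        pred = iv.model_predict(
            colistin, d, iv.IndividualRealization(np.zeros(3), kap)
        )
        base = iv.model_predict(colistin, d, colistin.zero_realization())
        assert pred[0] == pytest.approx(base[0] - math.log(2.0), abs=1e-10)

    def test_forbidden_window_samples_still_predicted(self, colistin):
        d = iv.design_from_times(colistin, [12.2, 13.0])
        assert not d.active_mask()[:2].any()
        pred = iv.model_predict(colistin, d, colistin.zero_realization())
        assert np.all(np.isfinite(pred))


class TestErrorSd:
    def test_formula_arithmetic(self, colistin):
        # prop=0.2, add=0.1, concentration denom=2, eta_ER=0
        import dataclasses

        cf = dataclasses.replace(
            colistin,
            error={**colistin.error, "CMS_prop": 0.2, "CMS_add": 0.1},
        )
        d = iv.Design(np.array([1.0]), np.array([0]), ())
        sd = cf.error_sd(d.times, d.channels, np.array([math.log(2.0)]), np.zeros(3))
        assert sd[0] == pytest.approx(math.sqrt(0.04 + 0.0025), rel=1e-12)

    def test_eta_er_scales_cms_channel_only(self, colistin):
        d = iv.design_from_times(colistin, [5.0])
        pred = iv.model_predict(colistin, d, colistin.zero_realization())
        eta = np.array([0.0, 0.0, math.log(2.0)])
        sd0 = colistin.error_sd(d.times, d.channels, pred, np.zeros(3))
        sd1 = colistin.error_sd(d.times, d.channels, pred, eta)
        assert sd1[0] == pytest.approx(2 * sd0[0], rel=1e-12)  # CMS channel
        assert sd1[1] == pytest.approx(sd0[1], rel=1e-12)  # colistin channel

    def test_onecomp_additive_sd_is_one_everywhere(self, onecomp):
        d = iv.design_from_times(onecomp, [0.0, 3.0, 23.0])
        pred = iv.model_predict(onecomp, d, onecomp.zero_realization())
        assert np.allclose(onecomp.error_sd(d.times, d.channels, pred, None), 1.0)

    def test_as_printed_denominator_singular_at_unit_concentration(self):
        cf = iv.colistin_fixture(error_denominator="logconc")
        d = iv.Design(np.array([1.0]), np.array([0]), ())
        with pytest.raises(ZeroDivisionError):
            cf.error_sd(d.times, d.channels, np.array([0.0]), np.zeros(3))


class TestOccasions:
    @pytest.mark.parametrize(
        "time,expected",
        [(0.0, 1), (11.99, 1), (12.0, 2), (35.9, 3), (36.0, 3)],
    )
    def test_half_open_convention(self, colistin, time, expected):
        assert iv.occasion_of(time, colistin.regimen) == expected

    def test_out_of_range_rejected(self, colistin):
        with pytest.raises(ValueError):
            iv.occasion_of(36.5, colistin.regimen)
        with pytest.raises(ValueError):
            iv.occasion_of(-1.0, colistin.regimen)


class TestBuildInflated:
    def test_onecomp_diagonal_sum_rule(self, onecomp):
        infl = iv.build_inflated(onecomp)
        assert np.allclose(np.diag(infl.omega), [0.125, 0.125])
        assert infl.pi is None
        assert infl.n_kappa == 0

    def test_colistin_printed_values_and_residual_unchanged(self, colistin):
        infl = iv.build_inflated(colistin)
        assert np.allclose(np.diag(infl.omega), [0.20, 3.26, 1.8])
        assert infl.error == colistin.error
        # the shared-eta scaling factor follows the re-estimated IIV
        assert infl.theta["sc"] == pytest.approx(math.sqrt(0.70 / 0.20), rel=1e-3)

    def test_inflated_fixture_predicts_without_iov(self, onecomp):
        infl = iv.build_inflated(onecomp)
        d = iv.design_from_times(infl, [1.0, 7.0])
        pred = iv.model_predict(infl, d, infl.zero_realization())
        base = iv.model_predict(onecomp, d, onecomp.zero_realization())
        assert np.allclose(pred, base)

    def test_missing_omega_star_rejected(self):
        toy = iv.linear_toy(omega=[[1.0]], pi=[[1.0]])
        with pytest.raises(KeyError):
            iv.build_inflated(toy)


class TestBatchedPredictions:
    """Batched parameter-set solves must agree with the scalar path."""

    def test_colistin_batch_matches_scalar(self, colistin):
        rng = np.random.default_rng(0)
        etas = rng.normal(0, 0.4, (6, 3))
        kaps = rng.normal(0, 0.3, (6, 3, 3))
        d = iv.design_from_times(colistin, [1.0, 6.0, 23.0, 35.0])
        fb = colistin.predict_batch(d.times, d.channels, etas, kaps)
        sb = colistin.error_sd_batch(d.times, d.channels, fb, etas)
        for i in range(6):
            assert np.allclose(
                fb[i], colistin.predict(d.times, d.channels, etas[i], kaps[i]),
                rtol=1e-10,
            )
            assert np.allclose(
                sb[i],
                colistin.error_sd(d.times, d.channels, fb[i], etas[i]),
                rtol=1e-12,
            )

    def test_onecomp_batch_matches_scalar(self, onecomp_combined):
        rng = np.random.default_rng(1)
        etas = rng.normal(0, 0.25, (6, 2))
        kaps = rng.normal(0, 0.25, (6, 4, 2))
        d = iv.design_from_times(onecomp_combined, [0.0, 5.0, 13.0, 24.0])
        fb = onecomp_combined.predict_batch(d.times, d.channels, etas, kaps)
        for i in range(6):
            assert np.allclose(
                fb[i],
                onecomp_combined.predict(d.times, d.channels, etas[i], kaps[i]),
                rtol=1e-10,
            )


class TestFixtureLoading:
    def test_invariants_of_bundled_fixtures(self, colistin, onecomp):
        assert len(colistin.channels) == 2
        assert all(ch.log_scale for ch in colistin.channels)
        assert len(onecomp.channels) == 1
        assert not onecomp.channels[0].log_scale
        assert colistin.omega_star is not None and onecomp.omega_star is not None

    def test_dose_scale_recorded(self, onecomp):
        assert onecomp.theta["dose_scale"] == 500.0
        assert onecomp.regimen.events[0].amount == 500.0

    def test_iiv_subset_restriction(self):
        fx = iv.onecomp_fixture(iiv=("CL",), iov=("CL",))
        assert fx.eta_names == ("CL",)
        assert fx.omega.shape == (1, 1)
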