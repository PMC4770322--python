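"""Quantum-efficiency images and per-pixel ETR / NPQ model fitting."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from biomemap import fluor, synthetic
from biomemap.fluor import (
    DEFAULT_LIGHT_STEPS,
    FluorStack,
    exclude_na,
    fit_npq_max,
    fit_platt,
    hill_npq,
    npq,
    platt_etr,
    quantum_efficiency,
)

E = np.asarray(DEFAULT_LIGHT_STEPS)


def make_stack(fo=0.2, fm=0.8, f=None, fm_prime=None, shape=(1, 1)):
    nsteps = E.size
    f = np.full((nsteps,) + shape, 0.3 if f is None else f)
    fm_prime = np.full((nsteps,) + shape, 0.6 if fm_prime is None else fm_prime)
    return FluorStack(
        light_steps=E,
        fo=np.full(shape, fo),
        fm=np.full(shape, fm),
        f=f,
        fm_prime=fm_prime,
    )


class TestPerStepImages:
    def test_fvfm_definition(self):
        eff = quantum_efficiency(make_stack(fo=0.2, fm=0.8))
        assert eff.fvfm[0, 0] == pytest.approx(0.75)

    def test_f_equal_fmprime_gives_zero_efficiency(self):
        eff = quantum_efficiency(make_stack(f=0.6, fm_prime=0.6))
        np.testing.assert_allclose(eff.fqfm, 0.0)

    def test_nonpositive_fmprime_becomes_na_and_is_counted(self):
        eff = quantum_efficiency(make_stack(fm_prime=0.0))
        assert np.all(np.isnan(eff.fqfm))
        assert eff.n_invalid > 0

    def test_out_of_range_flagged_not_clipped(self):
        eff = quantum_efficiency(make_stack(f=-0.1, fm_prime=0.5))
        assert np.all(eff.fqfm > 1.0)  # reported as-is
        assert eff.n_out_of_range == E.size

    def test_etr_direct_product_and_zero_irradiance(self):
        assert fluor.etr(np.array([[0.4]]), 100.0)[0, 0] == pytest.approx(20.0)
        assert fluor.etr(np.array([[0.4]]), 0.0)[0, 0] == 0.0

    def test_npq_definition(self):
        stack = make_stack(fm=0.8, fm_prime=0.4)
        np.testing.assert_allclose(npq(stack), 1.0)
        stack = make_stack(fm=0.6, fm_prime=0.6)
        np.testing.assert_allclose(npq(stack), 0.0)

    def test_npq_na_on_zero_fmprime(self):
        assert np.all(np.isnan(npq(make_stack(fm_prime=0.0))))


class TestPlattFit:
    def test_noiseless_recovery_at_printed_steps(self):
        alpha, etrmax = 0.3, 60.0
        y = platt_etr(E, alpha, etrmax)[:, None]
        fit = fit_platt(E, y)
        assert fit["alpha"][0] == pytest.approx(alpha, rel=1e-3)
        assert fit["etrmax"][0] == pytest.approx(etrmax, rel=1e-3)
        assert fit["ek"][0] == pytest.approx(etrmax / alpha, rel=1e-3)

    def test_ek_identity_is_exact_in_beta0_mode(self):
        rng = np.random.default_rng(1)
        y = platt_etr(E[:, None], 0.3, 60.0) * (1 + 0.02 * rng.standard_normal((E.size, 50)))
        fit = fit_platt(E, y)
        ok = np.isfinite(fit["ek"])
        np.testing.assert_array_equal(fit["ek"][ok], (fit["etrmax"] / fit["alpha"])[ok])

    def test_agrees_with_scipy_reference_fit(self, rng):
        """Batched LM vs scipy least_squares on the same noisy curves."""
        true = [(0.25, 40.0), (0.35, 70.0), (0.30, 55.0)]
        y = np.stack(
            [platt_etr(E, a, p) * (1 + 0.02 * rng.standard_normal(E.size)) for a, p in true],
            axis=1,
        )
        fit = fit_platt(E, y)
        for j, (a0, p0) in enumerate(true):
            ref = least_squares(
                lambda th: platt_etr(E, *np.exp(th)) - y[:, j], np.log([a0, p0])
            )
            a_ref, p_ref = np.exp(ref.x)
            assert fit["alpha"][j] == pytest.approx(a_ref, rel=1e-5)
            assert fit["etrmax"][j] == pytest.approx(p_ref, rel=1e-5)

    def test_linear_curve_flagged_ill_conditioned_alpha_kept(self):
        y = (0.3 * E)[:, None]  # never saturates within the protocol
        fit = fit_platt(E, y)
        assert fit["ill_conditioned"][0]
        assert fit["alpha"][0] == pytest.approx(0.3, rel=1e-3)
        assert np.isnan(fit["etrmax"][0]) and np.isnan(fit["ek"][0])

    def test_beta_mode_recovers_photoinhibited_curve(self):
        alpha, ps, beta = 0.3, 80.0, 0.02
        y = platt_etr(E, alpha, ps, beta)[:, None]
        fit = fit_platt(E, y, mode="beta")
        etrmax_true = fluor.platt_etrmax(alpha, ps, beta)
        assert fit["alpha"][0] == pytest.approx(alpha, rel=1e-3)
        assert fit["etrmax"][0] == pytest.approx(float(etrmax_true), rel=1e-3)

    def test_too_few_points_gives_na(self):
        y = platt_etr(E, 0.3, 60.0)[:, None].copy()
        y[3:] = np.nan
        fit = fit_platt(E, y)
        assert np.isnan(fit["alpha"][0]) and not fit["converged"][0]

    def test_low_light_limit_slope_equals_alpha(self):
        # closed-form property of the saturating model
        alpha, pm = 0.31, 55.0
        eps = 1e-6
        slope = platt_etr(eps, alpha, pm) / eps
        assert slope == pytest.approx(alpha, rel=1e-6)


class TestNpqFit:
    def test_noiseless_hill_recovery(self):
        y = hill_npq(E, 2.0, 150.0, 2.0)[:, None]
        fit = fit_npq_max(E, y)
        assert fit["npqmax"][0] == pytest.approx(2.0, rel=5e-3)
        assert fit["e50"][0] == pytest.approx(150.0, rel=1e-2)
        assert not fit["extrapolated"][0]

    def test_all_zero_npq_returns_zero_asymptote(self):
        fit = fit_npq_max(E, np.zeros((E.size, 1)))
        assert fit["npqmax"][0] == 0.0 and fit["converged"][0]

    def test_truncated_curve_raises_wide_confidence_flag(self):
        e_trunc = np.array([5.0, 20.0, 50.0, 80.0, 100.0])
        y = hill_npq(e_trunc, 2.0, 300.0, 2.0)[:, None]  # E50 beyond the range
        fit = fit_npq_max(e_trunc, y)
        assert fit["extrapolated"][0]

    def test_agrees_with_scipy_on_noiseless_curve(self):
        y = hill_npq(E, 1.4, 120.0, 1.7)[:, None]
        fit = fit_npq_max(E, y)
        ref = least_squares(
            lambda th: hill_npq(E, *np.exp(th)) - y[:, 0], np.log([1.0, 150.0, 2.0])
        )
        m_ref = np.exp(ref.x)[0]
        assert fit["npqmax"][0] == pytest.approx(m_ref, rel=1e-4)


class TestSceneRecovery:
    def test_noiseless_round_trip_below_0p1_percent(self):
        truth = synthetic.make_scene(seed=5, shape=(32, 32), warp="identity", noise_fluor=0.0)
        stack = synthetic.render_fluor_stack(truth)
        photo = fluor.fit_photomap(stack)
        m = truth.frond_mask
        for p in ("alpha", "etrmax", "npqmax"):
            err = np.abs(photo.parameter(p)[m] - truth.photo[p][m]) / truth.photo[p][m]
            assert np.nanmax(err) < 1e-3

    def test_recovery_error_degrades_monotonically_with_noise(self):
        truth = synthetic.make_scene(seed=6, shape=(32, 32), warp="identity")
        m = truth.frond_mask
        medians = []
        for sd in (0.0, 0.01, 0.02, 0.05):
            stack = synthetic.render_fluor_stack(truth, noise_sd=sd)
            photo = fluor.fit_photomap(stack)
            err = np.abs(photo.etrmax[m] - truth.photo["etrmax"][m]) / truth.photo["etrmax"][m]
            medians.append(np.nanmedian(err))
        assert all(b >= a - 1e-6 for a, b in zip(medians, medians[1:]))


class TestExcludeNa:
    def test_na_in_one_parameter_propagates_to_all(self):
        shape = (4, 4)
        grids = {p: np.ones(shape) for p in ("fvfm", "alpha", "ek", "etrmax", "npqmax")}
        grids["npqmax"][1, 2] = np.nan
        photo = fluor.PhotoMap(**grids)
        out = exclude_na(photo)
        for p in out._PARAMS:
            assert np.isnan(out.parameter(p)[1, 2])
        assert np.isfinite(out.alpha[0, 0])

    def test_identity_when_no_na(self):
        grids = {p: np.full((3, 3), 0.5) for p in ("fvfm", "alpha", "ek", "etrmax", "npqmax")}
        out = exclude_na(fluor.PhotoMap(**grids))
        for p in out._PARAMS:
            np.testing.assert_array_equal(out.parameter(p), 0.5)

    def test_all_na_map_stays_all_na(self):
        grids = {p: np.full((2, 2), np.nan) for p in ("fvfm", "alpha", "ek", "etrmax", "npqmax")}
        out = exclude_na(fluor.PhotoMap(**grids))
        assert np.all(np.isnan(out.alpha))


class TestStackValidation:
    def test_rejects_decreasing_light_steps(self):
        with pytest.raises(ValueError, match="increasing"):
            FluorStack(
                light_steps=[1, 3, 2, 4],
                fo=np.zeros((2, 2)),
                fm=np.ones((2, 2)),
                f=np.zeros((4, 2, 2)),
                fm_prime=np.ones((4, 2, 2)),
            )

    def test_rejects_layer_count_mismatch(self):
        with pytest.raises(ValueError, match="light step"):
            FluorStack(
                light_steps=[1, 2, 3, 4, 5],
                fo=np.zeros((2, 2)),
                fm=np.ones((2, 2)),
                f=np.zeros((4, 2, 2)),
                fm_prime=np.ones((4, 2, 2)),
            )
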