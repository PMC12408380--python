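"""Harmonic model, phenocycle reconstruction, and curve descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phenoasync as pa
from phenoasync.grid import timeline_365
from phenoasync.harmonic import (
    DAYS_PER_YEAR,
    build_design_matrix,
    fit_harmonic,
    nirv_from_reflectance,
)


def _random_series(rng, n_years=2, interval=4):
    t, doy = timeline_365(n_years=n_years, interval_days=interval)
    X = build_design_matrix(t, doy)
    beta = rng.normal(0, 1, 6)
    beta[1] = rng.normal(0, 1e-3)  # realistic small trend
    y = X @ beta + 0.1 * rng.standard_normal(t.size)
    return t, doy, y, beta


class TestNirv:
    def test_printed_definition(self):
        # NDVI = (0.3-0.1)/(0.3+0.1) = 0.5, NIR_V = 0.5*0.3 = 0.15
        assert nirv_from_reflectance(0.1, 0.3, 1e-4) == pytest.approx(0.15)

    @pytest.mark.parametrize("red,nir", [(0.3, 0.3), (0.3, 0.1)])
    def test_nonpositive_values_clamped(self, red, nir):
        assert nirv_from_reflectance(red, nir, 1e-4) == 1e-4

    def test_zero_total_reflectance_unavailable(self):
        assert np.isnan(nirv_from_reflectance(0.0, 0.0, 1e-4))


class TestDesignMatrix:
    def test_annual_term_wraps_at_day_365(self):
        X = build_design_matrix([0.0], [365])
        assert X[0, 2] == pytest.approx(0.0, abs=1e-12)  # sin
        assert X[0, 3] == pytest.approx(1.0, abs=1e-12)  # cos

    def test_semiannual_full_cycle_at_midyear(self):
        # 4*pi*doy/365 = 2*pi at doy 182.5; nearest integer days bracket it
        X = build_design_matrix([0.0, 0.0], [182, 183])
        assert np.all(X[:, 5] > 0.999)  # cos t_sem ~ 1

    def test_one_year_apart_shares_harmonics(self):
        X = build_design_matrix([0.0, 365.0], [40, 40])
        np.testing.assert_allclose(X[0, 2:], X[1, 2:], atol=1e-12)
        assert X[1, 1] - X[0, 1] == 365.0


class TestFit:
    def test_noise_free_exact_recovery(self):
        t, doy = timeline_365()
        X = build_design_matrix(t, doy)
        beta = np.array([0.3, 1e-4, 0.1, -0.05, 0.02, 0.04])
        fit = fit_harmonic(X @ beta, np.ones(t.size, bool), t, doy)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_series(self):
        t, doy = timeline_365()
        fit = fit_harmonic(np.full(t.size, 2.5), np.ones(t.size, bool), t, doy)
        assert fit.ok
        assert fit.b0 == pytest.approx(2.5)
        np.testing.assert_allclose([fit.bt, fit.b1, fit.b2, fit.b3, fit.b4], 0, atol=1e-10)
        assert fit.r2 == 0.0

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            t, doy, y, _ = _random_series(rng)
            avail = rng.random(t.size) > 0.2
            fit = fit_harmonic(y, avail, t, doy)
            X = build_design_matrix(t[avail], doy[avail])
            oracle = np.linalg.pinv(X) @ y[avail]
            np.testing.assert_allclose(fit.coefficients, oracle, rtol=1e-8, atol=1e-10)

    def test_too_few_observations_flagged(self):
        t, doy = timeline_365()
        avail = np.zeros(t.size, bool)
        avail[:10] = True
        fit = fit_harmonic(np.ones(t.size), avail, t, doy)
        assert not fit.ok

    def test_span_below_one_year_flagged(self):
        t, doy = timeline_365()
        avail = t < 200
        fit = fit_harmonic(np.sin(t / 20), avail, t, doy)
        assert not fit.ok

    def test_parameter_recovery_improves_with_n(self):
        """Mean absolute coefficient error shrinks roughly like 1/sqrt(n)."""
        rng = np.random.default_rng(3)
        errs = []
        for interval in (16, 4, 1):  # n grows by 4x each step
            t, doy = timeline_365(n_years=2, interval_days=interval)
            X = build_design_matrix(t, doy)
            beta = np.array([0.3, 0.0, 0.15, 0.0, 0.0, 0.0])
            e = []
            for _ in range(60):
                y = X @ beta + 0.015 * rng.standard_normal(t.size)  # 10% of amplitude
                fit = fit_harmonic(y, np.ones(t.size, bool), t, doy)
                e.append(np.abs(fit.coefficients[[0, 2, 3, 4, 5]] - beta[[0, 2, 3, 4, 5]]).mean())
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] > 2.0  # ~4x n twice over -> ~4x error reduction


class TestPhenocycle:
    def test_trend_does_not_affect_curve(self):
        a = pa.HarmonicFit(0.3, 0.0, 0.1, 0.05, 0.0, 0.02, 1.0, 100)
        b = pa.HarmonicFit(0.3, 5e-3, 0.1, 0.05, 0.0, 0.02, 1.0, 100)
        np.testing.assert_array_equal(
            pa.reconstruct_phenocycle(a).values, pa.reconstruct_phenocycle(b).values
        )

    def test_flat_curve_from_intercept_only(self):
        fit = pa.HarmonicFit(0.7, 0.0, 0, 0, 0, 0, 0.0, 100)
        np.testing.assert_allclose(pa.reconstruct_phenocycle(fit).values, 0.7)

    def test_pure_annual_cosine_peaks_at_year_boundary(self):
        fit = pa.HarmonicFit(0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0, 100)
        peak_day = np.argmax(pa.reconstruct_phenocycle(fit).values) + 1
        assert peak_day == 365  # cos(2*pi*d/365) maximal at the wrap

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(5)
        c1, c2 = rng.normal(size=6), rng.normal(size=6)
        f = lambda c: pa.reconstruct_phenocycle(
            pa.HarmonicFit(*c, r2=1.0, n_obs=50)
        ).values
        np.testing.assert_allclose(f(c1) + f(c2), f(c1 + c2), atol=1e-12)


class TestScaling:
    def test_standardize_moments(self):
        curve = pa.Phenocycle(np.sin(np.linspace(0, 7, 365)) + 3)
        s = pa.standardize(curve)
        assert abs(s.values.mean()) < 1e-12
        assert abs(s.values.std() - 1) < 1e-12

    def test_affine_invariance(self):
        v = np.cos(2 * np.pi * np.arange(365) / 365)
        a = pa.standardize(pa.Phenocycle(v))
        b = pa.standardize(pa.Phenocycle(3.0 * v + 17.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_minmax_attains_bounds(self):
        s = pa.minmax(pa.Phenocycle(np.sin(2 * np.pi * np.arange(365) / 365)))
        assert s.values.min() == 0.0 and s.values.max() == 1.0

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError):
            pa.standardize(pa.Phenocycle(np.ones(365)))
        with pytest.raises(ValueError):
            pa.minmax(pa.Phenocycle(np.ones(365)))


class TestUnimodality:
    @staticmethod
    def _cycle(b1=0.0, b2=0.0, b3=0.0, b4=0.0):
        return pa.reconstruct_phenocycle(pa.HarmonicFit(0, 0, b1, b2, b3, b4, 1.0, 50))

    def test_pure_annual_is_unimodal(self):
        assert pa.unimodality_index(self._cycle(b2=1.0)) == 1.0

    def test_pure_semiannual_is_evenly_bimodal(self):
        # integer-day sampling puts one peak on a 2-day plateau straddling
        # d = 182.5, whose height falls short of the exact d = 365 peak by
        # ~4e-5; the index is therefore ~0 rather than exactly 0
        assert pa.unimodality_index(self._cycle(b4=1.0)) == pytest.approx(0.0, abs=1e-3)

    def test_mixed_curve_matches_brute_force_scan(self):
        curve = self._cycle(b1=0.05, b2=0.3, b4=0.9)  # two peaks, unequal heights
        idx = pa.unimodality_index(curve)
        assert 0.0 < idx < 1.0
        # oracle: exhaustive circular neighbor comparison on the scaled curve
        v = pa.minmax(curve).values
        peaks = [
            v[i]
            for i in range(365)
            if v[i] > v[(i - 1) % 365] and v[i] > v[(i + 1) % 365]
        ]
        top = sorted(peaks, reverse=True)[:2]
        assert idx == pytest.approx(abs(top[0] - top[1]), abs=1e-12)

    @given(st.integers(min_value=0, max_value=364))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_rotation(self, offset):
        curve = self._cycle(b1=0.2, b2=0.4, b4=0.9)
        base = pa.unimodality_index(curve)
        rotated = pa.rotate_days(curve, offset)
        assert pa.unimodality_index(rotated) == pytest.approx(base, abs=1e-12)


class TestRotation:
    def test_identity(self):
        c = pa.Phenocycle(np.arange(365, dtype=float))
        np.testing.assert_array_equal(pa.rotate_days(c, 0).values, c.values)

    def test_double_half_year_is_one_day_short(self):
        c = pa.Phenocycle(np.arange(365, dtype=float))
        twice = pa.rotate_days(pa.rotate_days(c, 182), 182)
        np.testing.assert_array_equal(twice.values, np.roll(c.values, 364))

    def test_peak_day_shifts_by_offset(self):
        v = np.zeros(365)
        v[99] = 1.0
        shifted = pa.rotate_days(pa.Phenocycle(v), 50)
        assert np.argmax(shifted.values) == 149


class TestFitAgreement:
    def test_identical_curves(self):
        c = pa.Phenocycle(np.sin(2 * np.pi * np.arange(365) / 365))
        assert pa.fit_agreement(c, c) == pytest.approx(1.0)

    def test_negation_blind(self):
        v = np.sin(2 * np.pi * np.arange(365) / 365)
        assert pa.fit_agreement(pa.Phenocycle(v), pa.Phenocycle(-v)) == pytest.approx(1.0)

    def test_quarter_shift_orthogonal(self):
        v = np.sin(2 * np.pi * np.arange(365) / 365)
        shifted = np.roll(v, 91)
        assert pa.fit_agreement(pa.Phenocycle(v), pa.Phenocycle(shifted)) < 0.01

    def test_constant_rejected(self):
        v = np.sin(2 * np.pi * np.arange(365) / 365)
        with pytest.raises(ValueError):
            pa.fit_agreement(pa.Phenocycle(np.ones(365)), pa.Phenocycle(v))
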