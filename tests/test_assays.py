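import numpy as np
import pytest

from luxomics.assays import (
    AbsorbanceRecord,
    CtRecord,
    FrapTrace,
    KineticSeries,
    chlorophyll_content,
    delta_delta_ct,
    effector_fold_change,
    fit_frap,
    fit_michaelis_menten,
    half_recovery_time,
    normalize_frap,
    normalize_m6a_ratio,
    recovery_at,
    subtract_background,
)
from luxomics.assays import _frap_model

S5 = np.array([0.1, 0.5, 1.0, 2.0, 4.0])


def mm_series(km=1.0, vmax=10.0, noise=None, rng=None, reps=1, background=0.0, enzyme=1.0):
    v = vmax * S5 / (km + S5)
    rate = np.repeat(v[:, None], reps, axis=1)
    if noise:
        rate = rate * rng.lognormal(0, noise, rate.shape)
    return KineticSeries(S5, rate + background, background=background, enzyme_conc=enzyme)


class TestKinetics:
    def test_background_subtraction(self):
        s = KineticSeries(S5, np.array([10.0, 5.0, 3.0, 2.5, 1.0]), background=2.0)
        net = subtract_background(s)
        np.testing.assert_allclose(net.rate[:, 0], [8, 3, 1, 0.5, 0])
        assert net.background == 0.0

    def test_clipping_floor(self):
        s = KineticSeries(S5, np.full(5, 1.0), background=2.0)
        assert subtract_background(s).rate.min() == 0.0

    def test_noiseless_recovery(self):
        fit = fit_michaelis_menten(mm_series())
        assert fit.converged
        assert fit.km == pytest.approx(1.0, rel=1e-6)
        assert fit.vmax == pytest.approx(10.0, rel=1e-6)
        assert fit.kcat == pytest.approx(10.0, rel=1e-6)
        assert fit.catalytic_efficiency == pytest.approx(10.0, rel=1e-6)

    def test_half_saturation_identity(self):
        fit = fit_michaelis_menten(mm_series(km=0.8, vmax=6.0))
        v_at_km = fit.vmax * fit.km / (fit.km + fit.km)
        assert v_at_km == pytest.approx(fit.vmax / 2)

    def test_grid_search_oracle_agreement(self):
        """Coarse grid search over (Km, Vmax) lands on the same optimum."""
        series = mm_series(km=1.3, vmax=7.0)
        v = series.rate.mean(axis=1)
        grid_km = np.linspace(0.5, 3.0, 251)
        grid_vm = np.linspace(4.0, 10.0, 241)
        sse = [
            ((vm * S5 / (km + S5) - v) ** 2).sum()
            for km in grid_km for vm in grid_vm
        ]
        best = np.argmin(sse)
        km_hat, vm_hat = grid_km[best // 241], grid_vm[best % 241]
        fit = fit_michaelis_menten(series)
        assert fit.km == pytest.approx(km_hat, abs=0.02)
        assert fit.vmax == pytest.approx(vm_hat, abs=0.05)

    def test_noisy_recovery_median_error(self):
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(100):
            fit = fit_michaelis_menten(mm_series(noise=0.05, rng=rng, reps=3))
            errs.append([abs(fit.km - 1.0), abs(fit.vmax - 10.0) / 10.0])
        med = np.median(errs, axis=0)
        assert med[0] <= 0.15 and med[1] <= 0.15

    def test_all_zero_rates_flagged(self):
        fit = fit_michaelis_menten(KineticSeries(S5, np.zeros(5)))
        assert not fit.converged

    def test_kcat_uses_enzyme_concentration(self):
        fit = fit_michaelis_menten(mm_series(enzyme=2.0))
        assert fit.kcat == pytest.approx(5.0, rel=1e-6)

    def test_effector_fold_change(self):
        assert effector_fold_change(4.0, 2.0) == 2.0
        assert effector_fold_change(3.0, 3.0) == 1.0
        with pytest.raises(ValueError):
            effector_fold_change(1.0, 0.0)


FRAP_TRUE = dict(i0=0.85, alpha=0.5, beta=0.5, gamma=0.35, delta=0.05)


def frap_curve(t):
    return _frap_model(t, **FRAP_TRUE)


class TestFrapNormalization:
    def _trace(self, ref=None):
        t = np.arange(-5.0, 40.0)
        post = np.maximum(t, 0.0)
        bleached = np.where(t < 0, 100.0, 40.0 + 30 * (1 - np.exp(-0.3 * post)))
        reference = np.full(t.size, 60.0) if ref is None else ref
        return FrapTrace(t, bleached, reference, n_prebleach=5)

    def test_full_scale_endpoints(self):
        tt, y = normalize_frap(self._trace())
        assert y[0] == pytest.approx(0.0)
        assert tt[0] == 0.0

    def test_full_recovery_maps_to_one(self):
        t = np.arange(-5.0, 200.0)
        post = np.maximum(t, 0.0)
        bleached = np.where(t < 0, 100.0, 100.0 - 60 * np.exp(-0.5 * post))
        trace = FrapTrace(t, bleached, np.full(t.size, 60.0), n_prebleach=5)
        _, y = normalize_frap(trace)
        assert y[-1] == pytest.approx(1.0, abs=1e-6)

    def test_reference_ratio_cancellation(self):
        trace = self._trace()
        # equal multiplicative photobleach on both ROIs leaves the result unchanged
        decay = np.exp(-0.01 * np.arange(trace.time.size))
        faded = FrapTrace(
            trace.time, trace.bleached_roi * decay, trace.reference_roi * decay, trace.n_prebleach
        )
        t1, y1 = normalize_frap(trace)
        t2, y2 = normalize_frap(faded)
        np.testing.assert_allclose(y1, y2, atol=1e-12)

    def test_no_bleach_depth_errors(self):
        t = np.arange(-5.0, 10.0)
        flat = FrapTrace(t, np.full(t.size, 100.0), np.full(t.size, 50.0), n_prebleach=5)
        with pytest.raises(ValueError, match="bleach"):
            normalize_frap(flat)

    def test_zero_reference_errors(self):
        t = np.arange(-5.0, 10.0)
        ref = np.full(t.size, 50.0)
        ref[3] = 0.0
        with pytest.raises(ValueError, match="reference"):
            normalize_frap(FrapTrace(t, np.full(t.size, 100.0), ref, n_prebleach=5))


class TestFrapFit:
    def test_noiseless_parameter_recovery(self):
        t = np.arange(0.0, 60.0)
        fit = fit_frap(t, frap_curve(t))
        for name, true in FRAP_TRUE.items():
            assert getattr(fit, name) == pytest.approx(true, rel=1e-4), name

    def test_mobile_fraction_is_plateau(self):
        t = np.arange(0.0, 60.0)
        fit = fit_frap(t, frap_curve(t))
        assert fit.mobile_fraction == fit.i0
        assert recovery_at(fit, np.inf) == fit.mobile_fraction

    def test_recovery_at_closed_form(self):
        t = np.arange(0.0, 60.0)
        fit = fit_frap(t, frap_curve(t))
        expected = 0.85 - 0.5 * np.exp(-0.5 * 20) - 0.35 * np.exp(-0.05 * 20)
        assert recovery_at(fit, 20.0) == pytest.approx(expected, rel=1e-4)
        assert recovery_at(fit, 0.0) == pytest.approx(0.85 - 0.5 - 0.35, abs=1e-6)

    def test_fitted_curve_monotone_for_nonnegative_amplitudes(self):
        t = np.arange(0.0, 60.0)
        fit = fit_frap(t, frap_curve(t))
        dense = np.linspace(0, 120, 2000)
        vals = [recovery_at(fit, x) for x in dense]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_component_order_beta_ge_delta(self):
        t = np.arange(0.0, 60.0)
        fit = fit_frap(t, frap_curve(t))
        assert fit.beta >= fit.delta >= 0

    def test_noisy_i0_recovery(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 60.0)
        errs = []
        for _ in range(50):
            y = frap_curve(t) + rng.normal(0, 0.02, t.size)
            fit = fit_frap(t, y)
            errs.append(abs(fit.i0 - 0.85) / 0.85)
        assert np.median(errs) <= 0.10

    def test_flat_trace_not_converged(self):
        t = np.arange(0.0, 20.0)
        fit = fit_frap(t, np.zeros(t.size))
        assert not fit.converged

    def test_half_recovery_time(self):
        t = np.arange(0.0, 60.0)
        fit = fit_frap(t, frap_curve(t))
        th = half_recovery_time(fit)
        mid = recovery_at(fit, 0.0) + 0.5 * (fit.i0 - recovery_at(fit, 0.0))
        assert recovery_at(fit, th) == pytest.approx(mid, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_frap(np.arange(5.0), np.zeros(5))


class TestChlorophyll:
    def test_unit_absorbance_coefficients(self):
        a = chlorophyll_content(AbsorbanceRecord(a646=0.0, a663=1.0))
        b = chlorophyll_content(AbsorbanceRecord(a646=1.0, a663=0.0))
        assert a["chl_a_ug_ml"] == 12.21
        assert b["chl_b_ug_ml"] == 20.13
        assert a["chl_b_ug_ml"] == -5.03 and a["warning"]
        assert b["chl_a_ug_ml"] == -2.81 and b["warning"]

    def test_zero_absorbance_zero_content(self):
        r = chlorophyll_content(AbsorbanceRecord(0.0, 0.0))
        assert r["total_ug_ml"] == 0.0 and not r["warning"]

    def test_exact_linearity(self):
        r1 = chlorophyll_content(AbsorbanceRecord(0.3, 0.8))
        r3 = chlorophyll_content(AbsorbanceRecord(0.9, 2.4))
        assert r3["chl_a_ug_ml"] == pytest.approx(3 * r1["chl_a_ug_ml"])
        assert r3["total_mg_g_fw"] == pytest.approx(3 * r1["total_mg_g_fw"])

    def test_per_fresh_weight_units(self):
        r = chlorophyll_content(AbsorbanceRecord(0.5, 1.0, fresh_weight=0.2, extract_volume=10.0))
        assert r["total_mg_g_fw"] == pytest.approx(r["total_ug_ml"] * 10.0 / 0.2 / 1000.0)


class TestCtAndRatios:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 20, 20, 20), 1.0),
            ((19, 20, 20, 20), 2.0),  # ddCt = -1
            ((22, 20, 20, 20), 0.25),  # ddCt = +2
        ],
    )
    def test_ddct(self, cts, expected):
        assert delta_delta_ct(CtRecord(*cts)) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            CtRecord(np.nan, 20, 20, 20)

    def test_m6a_ratio_normalization(self):
        out = normalize_m6a_ratio({"WT": 0.008, "mut": 0.006}, "WT")
        assert out == {"WT": 1.0, "mut": 0.75}
        assert normalize_m6a_ratio({"WT": 0.5}) == {"WT": 1.0}
        with pytest.raises(ValueError):
            normalize_m6a_ratio({"WT": 0.0}, "WT")
        with pytest.raises(KeyError):
            normalize_m6a_ratio({"mut": 1.0}, "WT")


class TestSeriesValidation:
    def test_needs_four_distinct_concentrations(self):
        with pytest.raises(ValueError):
            KineticSeries(np.array([1.0, 1.0, 2.0, 2.0]), np.ones(4))

    def test_frap_times_strictly_increasing(self):
        with pytest.raises(ValueError):
            FrapTrace(np.array([0.0, 0.0, 1.0]), np.ones(3), np.ones(3), 1)
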