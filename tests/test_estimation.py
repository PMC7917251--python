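"""IVGTT fitting: recovery, precision, identifiability, weighting."""

import numpy as np
import pytest

import minmod as mm
from minmod.errors import DataError, IdentifiabilityError, ParameterError
from minmod.estimation import _fsd_from_jacobian


class TestNoiselessRecovery:
    def test_all_parameters_within_0p1_percent(self, clean_fit, normal_params):
        """Self-consistency: fitting exact model data returns the truth."""
        for name in ("p1", "p2", "p3", "G0"):
            est = getattr(clean_fit.params, name)
            true = getattr(normal_params, name)
            assert est == pytest.approx(true, rel=1e-3), name

    def test_fsd_tiny_on_noiseless_data(self, clean_fit):
        assert all(f < 0.01 for f in clean_fit.fsd.values())

    def test_converged_off_bounds(self, clean_fit):
        assert clean_fit.converged
        assert clean_fit.boundary_params == ()


class TestGridSearchOracle:
    def test_p1_g0_optimum_matches_exhaustive_grid(self, normal_params):
        """With p2, p3 frozen at truth, the optimizer's (p1, G0) optimum must
        land in the best cell of a 200x200 exhaustive grid search.

        The oracle is an independent quadrature solution: X(t) from
        fine-step Euler, then the variation-of-constants formula
        G(t) = e^(-p1 t - A(t)) (G0 + p1 Gb B(t)) with A = int X and
        B = int e^(p1 s + A(s)) ds evaluated by trapezoid.
        """
        truth = normal_params
        rec = mm.generate_ivgtt(truth, noise_cv=(0.02, 0.0), seed=99)
        gb, ib = rec.basal()
        opts = mm.FitOptions(fix={"p2": truth.p2, "p3": truth.p3})
        fit = mm.fit_minimal_model(rec, opts)

        # fine grid and Euler X(t) from the same sampled insulin input
        dt_e = 2e-3
        te = np.arange(0.0, 180.0 + dt_e / 2, dt_e)
        di = np.interp(te, rec.times, rec.insulin) - ib
        x = np.empty_like(te)
        x[0] = 0.0
        for i in range(te.size - 1):
            x[i + 1] = x[i] + dt_e * (-truth.p2 * x[i] + truth.p3 * di[i])
        tq = te[::5]  # 0.01-min quadrature grid
        xq = x[::5]
        a = np.concatenate(([0.0], np.cumsum(0.5 * (xq[1:] + xq[:-1]) * np.diff(tq))))

        mask = rec.times >= 8.0
        t_obs = rec.times[mask]
        y = rec.glucose[mask]
        sigma = 0.02 * y
        idx = np.searchsorted(tq, t_obs)
        assert np.allclose(tq[idx], t_obs)

        p1_grid = np.linspace(0.01, 0.04, 200)
        g0_grid = np.linspace(220.0, 340.0, 200)
        best = (np.inf, None, None)
        for p1 in p1_grid:
            w = np.exp(p1 * tq + a)
            b = np.concatenate(([0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(tq))))
            alpha = np.exp(-p1 * tq - a)[idx]
            beta = alpha * p1 * gb * b[idx]
            # residuals are linear in G0: vectorize the G0 sweep
            r0 = (beta - y) / sigma
            r1 = alpha / sigma
            ssr = (
                (r0 @ r0)
                + 2.0 * (r0 @ r1) * g0_grid
                + (r1 @ r1) * g0_grid**2
            )
            j = int(np.argmin(ssr))
            if ssr[j] < best[0]:
                best = (ssr[j], p1, g0_grid[j])

        cell_p1 = p1_grid[1] - p1_grid[0]
        cell_g0 = g0_grid[1] - g0_grid[0]
        assert fit.ssr <= best[0] + 1e-6
        assert abs(fit.params.p1 - best[1]) <= cell_p1
        assert abs(fit.params.G0 - best[2]) <= cell_g0


class TestComputeSI:
    def test_zero_gain(self, normal_params):
        assert mm.compute_SI(normal_params.replace(p3=0.0)) == 0.0

    def test_ratio_arithmetic(self):
        p = mm.MinimalModelParams(p1=0.02, p2=0.03, p3=1.5e-5, Gb=90, Ib=10, G0=280)
        assert mm.compute_SI(p) == pytest.approx(5.0e-4, rel=1e-12)

    def test_equals_unit_step_steady_state_gain(self, normal_params):
        """Cross-module identity: SI is the X steady state per unit insulin."""
        x = mm.steady_state_remote_insulin(normal_params, normal_params.Ib + 1.0)
        assert mm.compute_SI(normal_params) == pytest.approx(x, rel=1e-12)


class TestPrecision:
    def test_refit_is_deterministic(self, clean_record, clean_fit):
        again = mm.fit_minimal_model(clean_record)
        assert again.fsd == clean_fit.fsd
        assert again.params == clean_fit.params

    def test_unexcited_remote_compartment_not_identified(self, normal_params):
        """Insulin pinned at basal never excites X: p2, p3 are structurally
        unidentifiable and must be flagged."""
        t = mm.default_schedule()
        p = normal_params
        g = np.where(t < 0, p.Gb, p.Gb + (p.G0 - p.Gb) * np.exp(-p.p1 * np.maximum(t, 0.0)))
        rec = mm.IVGTTRecord("flat", t, g, np.full(t.size, p.Ib))
        fit = mm.fit_minimal_model(rec)
        table = mm.parameter_precision(fit, report_only=True)
        assert not table["p2"]["identified"]
        assert not table["p3"]["identified"]
        assert table["p1"]["identified"]
        with pytest.raises(IdentifiabilityError):
            mm.parameter_precision(fit)

    def test_weighting_invariance_under_rescaling(self, normal_params):
        """Scaling all glucose (and Gb) by a constant leaves SI, SG and the
        weighted SSR unchanged under relative-error weighting."""
        rec = mm.generate_ivgtt(normal_params, noise_cv=0.02, seed=17)
        c = 2.5  # keeps the scaled G0 inside the default fit bounds
        scaled = mm.IVGTTRecord(
            rec.subject_id, rec.times, rec.glucose * c, rec.insulin, noise_cv=rec.noise_cv
        )
        f1 = mm.fit_minimal_model(rec)
        f2 = mm.fit_minimal_model(scaled)
        assert f2.SI == pytest.approx(f1.SI, rel=1e-6)
        assert f2.params.p1 == pytest.approx(f1.params.p1, rel=1e-6)
        assert f2.ssr == pytest.approx(f1.ssr, rel=1e-6)
        assert f2.params.G0 == pytest.approx(c * f1.params.G0, rel=1e-6)

    def test_modified_protocol_sharpens_si_in_low_responders(self):
        """For an insulin-resistant subject with an inadequate first-phase
        response, the 20-min secondary insulin peak tightens the SI estimate
        (smaller FSD of ln SI) on every matched noise seed."""
        resistant = mm.NORMAL_SUBJECT.replace(p3=1e-4 * 0.03)
        tpl = mm.InsulinCurveTemplate(peak_height=15.0)
        tpl_mod = tpl.modified()
        for seed in range(8100, 8106):
            ru = mm.generate_ivgtt(resistant, template=tpl, noise_cv=0.02, seed=seed)
            rm = mm.generate_ivgtt(resistant, template=tpl_mod, noise_cv=0.02, seed=seed)
            fu = mm.fit_minimal_model(ru)
            fm = mm.fit_minimal_model(rm)

            def fsd_ln_si(fit):
                _, cov, _ = _fsd_from_jacobian(fit.jac_log, fit.s2)
                i2 = fit.free_names.index("p2")
                i3 = fit.free_names.index("p3")
                return np.sqrt(max(cov[i3, i3] + cov[i2, i2] - 2 * cov[i3, i2], 0.0))

            assert fsd_ln_si(fm) <= fsd_ln_si(fu), seed


class TestInputValidation:
    def test_too_few_samples_in_window(self, normal_params):
        sched = np.array([-10.0, -5.0] + list(np.arange(0.0, 20.0, 2.0)))
        rec = mm.generate_ivgtt(normal_params, schedule=sched, noise_cv=0.0, seed=3)
        with pytest.raises(DataError):
            mm.fit_minimal_model(rec)

    def test_cannot_fix_unknown_parameter(self, clean_record):
        with pytest.raises(ParameterError):
            mm.fit_minimal_model(clean_record, mm.FitOptions(fix={"Gb": 90.0}))
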