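import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemosyn as cs
from chemosyn.hill import (
    BootstrapError,
    FitOptions,
    HillFit,
    NoDoseEffectError,
    fit_hill,
    fit_hill_global,
    fold_potency_change,
    hill_response,
    ic50_confidence,
)


class TestHillResponse:
    def test_half_maximal_identity(self):
        # at the IC50 the response is exactly Emax/2, whatever the slope
        assert hill_response(14.4, 88.0, np.log10(14.4), 1.0) == pytest.approx(44.0)
        assert hill_response(3.3, 57.0, np.log10(3.3), 2.7) == pytest.approx(28.5)

    def test_hand_evaluated_point(self):
        # 100 / (1 + (10/100)^2)
        assert hill_response(100.0, 100.0, 1.0, 2.0) == pytest.approx(100 / 1.01)

    def test_zero_conc_is_limit_zero(self):
        assert hill_response(0.0, 88.0, 1.0, 1.2) == 0.0

    def test_negative_conc_rejected(self):
        with pytest.raises(ValueError):
            hill_response(-1.0, 88.0, 1.0, 1.2)
        with pytest.raises(ValueError):
            hill_response(1.0, 88.0, 1.0, -2.0)

    @given(
        emax=st.floats(10, 120),
        l50=st.floats(-1, 2.5),
        slope=st.floats(0.2, 5),
        data=st.data(),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_concentration(self, emax, l50, slope, data):
        c1 = data.draw(st.floats(1e-3, 1e3))
        c2 = data.draw(st.floats(1e-3, 1e3))
        lo, hi = sorted((c1, c2))
        assert hill_response(lo, emax, l50, slope) <= hill_response(hi, emax, l50, slope) + 1e-12

    def test_limits(self):
        assert hill_response(1e9, 88.0, 1.0, 1.2) == pytest.approx(88.0, rel=1e-6)
        assert hill_response(1e-9, 88.0, 1.0, 1.2) == pytest.approx(0.0, abs=1e-6)


class TestFitHill:
    def test_noiseless_recovery(self, noiseless_curve):
        conc, resp, (emax, ic50, slope) = noiseless_curve
        fit = fit_hill((conc, resp), FitOptions(n_boot=0))
        assert fit.converged
        assert fit.ic50 == pytest.approx(ic50, rel=1e-2)
        assert fit.emax == pytest.approx(emax, rel=1e-3)
        assert fit.hill_slope == pytest.approx(slope, rel=1e-3)

    @given(
        emax=st.floats(50, 100),
        ic50=st.floats(0.5, 400),
        slope=st.floats(0.5, 3),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_round_trip_zero_noise(self, emax, ic50, slope):
        # noiseless data over a bracketing grid returns all three parameters
        conc = np.geomspace(ic50 / 20, ic50 * 20, 9)
        resp = hill_response(conc, emax, np.log10(ic50), slope)
        fit = fit_hill((conc, resp), FitOptions(n_boot=0), compute_cl=False)
        assert fit.converged
        assert fit.emax == pytest.approx(emax, rel=1e-3)
        assert fit.ic50 == pytest.approx(ic50, rel=1e-3)
        assert fit.hill_slope == pytest.approx(slope, rel=1e-3)

    def test_flat_zero_responses_error(self):
        conc = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        with pytest.raises(NoDoseEffectError):
            fit_hill((conc, np.zeros_like(conc)), FitOptions(n_boot=0))

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_hill(([1.0, 2.0, 5.0], [10.0, 20.0, 40.0]), FitOptions(n_boot=0))

    def test_zero_conc_wells_excluded(self, noiseless_curve):
        conc, resp, (emax, ic50, slope) = noiseless_curve
        conc2 = np.concatenate([[0.0, 0.0], conc])
        resp2 = np.concatenate([[0.0, 0.0], resp])
        fit = fit_hill((conc2, resp2), FitOptions(n_boot=0), compute_cl=False)
        assert fit.n_points == len(conc)
        assert fit.ic50 == pytest.approx(ic50, rel=1e-3)

    def test_fix_emax(self, noiseless_curve):
        conc, resp, (emax, ic50, slope) = noiseless_curve
        fit = fit_hill((conc, resp), FitOptions(n_boot=0, fix_emax_at=88.0), compute_cl=False)
        assert fit.emax == 88.0
        assert fit.ic50 == pytest.approx(ic50, rel=1e-3)


class TestConfidenceLimits:
    def test_noiseless_interval_degenerate(self, noiseless_curve):
        conc, resp, (_, ic50, _) = noiseless_curve
        c = np.repeat(conc, 3)
        r = np.repeat(resp, 3)
        fit = fit_hill((c, r), FitOptions(n_boot=100, seed=1))
        lo, hi = fit.ic50_cl
        assert lo == pytest.approx(ic50, rel=1e-3)
        assert hi == pytest.approx(ic50, rel=1e-3)

    def test_bootstrap_reproducible(self, noiseless_curve):
        conc, resp, _ = noiseless_curve
        rng = np.random.default_rng(7)
        c = np.repeat(conc, 6)
        r = np.repeat(resp, 6) + rng.normal(0, 6.0, conc.size * 6)
        opts = FitOptions(n_boot=80, seed=42)
        f1 = fit_hill((c, r), opts)
        f2 = fit_hill((c, r), opts)
        assert f1.ic50_cl == f2.ic50_cl
        assert f1.ic50_cl[0] <= f1.ic50 <= f1.ic50_cl[1]

    def test_asymptotic_fallback_brackets_estimate(self, noiseless_curve):
        conc, resp, _ = noiseless_curve
        rng = np.random.default_rng(3)
        c = np.repeat(conc, 6)
        r = np.repeat(resp, 6) + rng.normal(0, 6.0, c.size)
        fit = fit_hill((c, r), FitOptions(n_boot=0))
        lo, hi = fit.ic50_cl
        assert fit.cl_method == "asymptotic"
        assert lo < fit.ic50 < hi

    def test_interval_width_monotone_in_noise(self, noiseless_curve):
        # median bootstrap CL width never shrinks as plate noise grows
        conc, resp, _ = noiseless_curve
        c = np.repeat(conc, 6)
        base = np.repeat(resp, 6)
        widths = []
        for sd in (0.0, 6.0, 12.0):
            per_seed = []
            for seed in range(5):
                rng = np.random.default_rng(100 + seed)
                r = base + rng.normal(0, sd, c.size)
                fit = fit_hill((c, r), FitOptions(n_boot=60, seed=seed))
                lo, hi = fit.ic50_cl
                per_seed.append(hi - lo)
            widths.append(np.median(per_seed))
        assert widths[0] <= widths[1] + 1e-9 <= widths[2] + 1e-9

    def test_nonconverged_fit_rejected(self, noiseless_curve):
        conc, resp, _ = noiseless_curve
        bad = HillFit(88, 1.0, 1.2, (np.nan, np.nan), 7, 0.0, converged=False)
        with pytest.raises(ValueError):
            ic50_confidence((conc, resp), bad, FitOptions())


class TestGlobalFit:
    def test_shared_shape_recovers_shifted_curves(self):
        emax, slope = 90.0, 1.5
        ic50s = [197.0, 113.0, 379.5]
        grid = np.array([2.5, 10, 25, 50, 125, 250, 375, 500.0])
        datasets = [
            (grid, hill_response(grid, emax, np.log10(i), slope)) for i in ic50s
        ]
        fits = fit_hill_global(datasets, FitOptions(n_boot=0))
        assert all(f.converged for f in fits)
        assert fits[0].emax == pytest.approx(emax, rel=1e-4)
        assert fits[0].hill_slope == pytest.approx(slope, rel=1e-4)
        for f, i in zip(fits, ic50s):
            assert f.ic50 == pytest.approx(i, rel=1e-3)
        # shape parameters are literally shared
        assert len({f.emax for f in fits}) == 1
        assert len({f.hill_slope for f in fits}) == 1


class TestFoldPotency:
    def test_table_fold_changes(self):
        f24 = HillFit.from_ic50(14.4)
        f72 = HillFit.from_ic50(1.6)
        assert fold_potency_change(f24, f72) == pytest.approx(9.0)
        assert fold_potency_change(f24, f24) == pytest.approx(1.0)
        single = HillFit.from_ic50(13.6)
        double = HillFit.from_ic50(11.6)
        assert round(fold_potency_change(single, double), 1) == 1.2

    def test_nonconverged_rejected(self):
        good = HillFit.from_ic50(10.0)
        bad = HillFit(88, 1.0, 1.2, (np.nan, np.nan), 0, 0.0, converged=False)
        with pytest.raises(ValueError):
            fold_potency_change(good, bad)
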