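"""Binding models: closed forms, regime logic, single and global fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from crafruk import binding
from crafruk.binding import (
    BindingCurveFit,
    GlobalBindingFit,
    TitrationCurve,
    classify_regime,
    eq1_signal,
    eq2_signal,
    fit_global,
    fit_single_curve,
)


@pytest.mark.parametrize(
    "x, kd, c, ymax, expected",
    [
        (-9.0, 1e-9, 0.0, 2.0, 1.0),                 # half-saturation at L = Kd
        (-15.0, 1e-9, 0.1, 1.0, 0.100001),           # zero-ligand limit -> baseline
        (np.log10(6e-9), 2e-9, 0.0, 1.0, 0.75),      # 6/(2+6)
    ],
)
def test_hyperbolic_model_closed_forms(x, kd, c, ymax, expected):
    assert eq1_signal(x, kd, c, ymax) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "x, kd, dt, c, ymax, expected, tol",
    [
        (-30.0, 2e-9, 2e-9, 0.3, 1.0, 0.3, 1e-9),                      # zero titrant -> baseline
        (np.log10(2e-9), 1e-30, 2e-9, 0.0, 1.0, 1.0, 1e-6),            # Kd -> 0 at L = DT: fully bound
        (np.log10(2e-9), 2e-9, 2e-9, 0.0, 1.0, (3 - np.sqrt(5)) / 2, 1e-12),
    ],
)
def test_depletion_model_closed_forms(x, kd, dt, c, ymax, expected, tol):
    assert eq2_signal(x, kd, dt, c, ymax) == pytest.approx(expected, abs=tol)


def test_domain_errors():
    with pytest.raises(ValueError):
        eq1_signal(-9, kd=0.0)
    with pytest.raises(ValueError):
        eq2_signal(-9, kd=1e-9, dt=0.0)
    with pytest.raises(ValueError):
        eq2_signal(-9, kd=1e-9, dt=1e-9, n=0.0)
    with pytest.raises(ValueError):
        classify_regime(-1e-9, 1e-9)


@pytest.mark.parametrize(
    "dt, kd, label",
    [
        (2e-9, 2e-9, "intermediate"),       # assay conditions: DT near Kd
        (1e-10, 2e-9, "equilibrium"),       # ratio 0.05
        (2e-8, 2e-9, "stoichiometric"),     # ratio exactly 10: boundary goes outward
        (2e-10, 2e-9, "equilibrium"),       # ratio exactly 0.1: boundary goes outward
    ],
)
def test_regime_classification(dt, kd, label):
    assert classify_regime(dt, kd).label == label


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    log_kd=st.floats(-11, -6),
    log_dt=st.floats(-11, -7),
    c=st.floats(-0.5, 0.5),
    ymax=st.floats(0.1, 3.0),
)
def test_models_monotone_and_bounded(log_kd, log_dt, c, ymax):
    """Both models are non-decreasing in titrant and bounded by [c, c+Ymax]."""
    x = np.linspace(-13, -4, 200)
    for y in (
        eq1_signal(x, 10**log_kd, c, ymax),
        eq2_signal(x, 10**log_kd, 10**log_dt, c, ymax),
    ):
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y >= c - 1e-9) and np.all(y <= c + ymax + 1e-9)


def test_depletion_model_collapses_to_hyperbola_in_dilute_limit():
    """At DT = Kd * 1e-4 the quadratic model equals the hyperbola to <1e-3."""
    kd = 2e-9
    x = np.linspace(np.log10(kd) - 3, np.log10(kd) + 3, 400)
    y1 = eq1_signal(x, kd, 0.0, 1.0)
    y2 = eq2_signal(x, kd, kd * 1e-4, 0.0, 1.0)
    assert np.max(np.abs(y2 - y1) / np.abs(y1)) < 1e-3


def test_titration_curve_validation():
    with pytest.raises(ValueError, match=">= 4 points"):
        TitrationCurve("a", x=[-9, -8, -7], y=[0, 1, 2])
    with pytest.raises(ValueError, match="distinct"):
        TitrationCurve("a", x=[-9] * 5, y=[0, 1, 2, 3, 4])
    with pytest.raises(ValueError, match="non-finite"):
        TitrationCurve("a", x=[-9, -8, np.inf, -6], y=[0, 1, 2, 3])


class TestSingleCurveFit:
    def test_noiseless_hyperbola_recovery(self):
        kd = 1e-8
        x = np.linspace(-10, -6, 12)
        y = eq1_signal(x, kd, c=0.05, ymax=0.8)
        fit = BindingCurveFit(model="eq1").fit(x[:, None], y)
        assert fit.kd_ == pytest.approx(kd, rel=1e-3)
        assert fit.c_ == pytest.approx(0.05, abs=1e-6)
        assert fit.ymax_ == pytest.approx(0.8, rel=1e-4)
        assert fit.converged_ and fit.identifiable_

    def test_constant_signal_flags_non_identifiable(self):
        x = np.linspace(-10, -6, 8)
        y = np.full_like(x, 0.4)
        fit = BindingCurveFit(model="eq1").fit(x[:, None], y)
        assert not fit.identifiable_

    def test_depletion_bias_of_wrong_model(self):
        """Fitting hyperbola to depleting data at DT = 10*Kd inflates Kd.

        The apparent Kd is compared against a grid-search oracle that
        solves the linear (c, Ymax) subproblem exactly at each Kd.
        """
        kd, dt = 1e-9, 1e-8
        x = np.linspace(-11, -6, 15)
        y = eq2_signal(x, kd, dt, c=0.0, ymax=1.0)
        fit = BindingCurveFit(model="eq1").fit(x[:, None], y)

        # oracle: profile RSS over a log-spaced Kd grid, linear LS in c, Ymax
        grid = np.logspace(-10.5, -6.5, 2001)
        best_kd, best_rss = None, np.inf
        for kd_g in grid:
            basis = 10**x / (kd_g + 10**x)
            A = np.column_stack([np.ones_like(x), basis])
            coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((A @ coef - y) ** 2))
            if rss < best_rss:
                best_kd, best_rss = kd_g, rss
        assert fit.kd_ == pytest.approx(best_kd, rel=0.01)
        assert fit.kd_ > 2 * kd  # strongly biased upward vs truth

    def test_wrapper_accepts_fixed_params(self, noiseless_curves):
        curves, truth, spec = noiseless_curves
        c = curves[0]
        fit = fit_single_curve(c, model="eq2", fixed={"n": 1.0, "DT": c.dt_hint})
        assert fit.kd_ == pytest.approx(spec.true_kd, rel=1e-3)


class TestGlobalFit:
    def test_recovers_shared_kd_under_study_conditions(self, titration_set):
        curves, truth = titration_set
        fit = fit_global(curves)
        assert fit.converged_
        assert abs(fit.kd_ - 2.0e-9) < 0.5e-9
        assert len(fit.per_curve_) == 10
        # per-curve parameter count: c, ymax, dt for each curve
        assert {"c", "ymax", "dt_M"} <= set(fit.per_curve_.columns)

    def test_requires_two_curves(self, titration_set):
        curves, _ = titration_set
        X, y, hints = GlobalBindingFit.from_curves(curves[:1])
        with pytest.raises(ValueError, match=">= 2 curves"):
            GlobalBindingFit().fit(X, y)

    def test_duplicated_curve_matches_single_fit(self, noiseless_curves):
        curves, truth, spec = noiseless_curves
        c = curves[0]
        dup = [c, TitrationCurve("copy", c.x, c.y, c.dt_hint)]
        gfit = fit_global(dup)
        sfit = fit_single_curve(c, model="eq2", fixed={"n": 1.0})
        assert gfit.kd_ == pytest.approx(sfit.kd_, rel=1e-3)

    def test_matches_profile_likelihood_grid(self, noiseless_curves):
        """Global optimum agrees with a 1-D profile-RSS scan over log10 Kd."""
        curves, truth, spec = noiseless_curves
        gfit = fit_global(curves)

        def profile_rss(kd):
            total = 0.0
            for c in curves:
                def resid(theta):
                    return eq2_signal(c.x, kd, 10 ** theta[2], theta[0], theta[1]) - c.y
                y0 = [c.y.min(), c.y.max() - c.y.min(), np.log10(c.dt_hint)]
                res = least_squares(resid, y0, bounds=([-np.inf, -np.inf, -14], [np.inf, np.inf, -4]))
                total += 2 * res.cost
            return total

        grid = 10 ** np.arange(
            np.log10(spec.true_kd) - 0.05, np.log10(spec.true_kd) + 0.05, 0.001
        )
        rss = np.array([profile_rss(k) for k in grid])
        kd_grid = grid[np.argmin(rss)]
        assert abs(np.log10(gfit.kd_) - np.log10(kd_grid)) < 0.002
        assert gfit.rss_ <= rss.min() + 1e-10

    def test_pooled_rss_never_beats_global_optimum(self, titration_set):
        """Single-curve fits pinned to any common Kd cannot undercut the
        global fit's pooled RSS (objective consistency)."""
        curves, truth = titration_set
        gfit = fit_global(curves)
        for kd_common in (1.0e-9, 2.0e-9, 4.0e-9):
            pooled = 0.0
            for c in curves:
                def resid(theta):
                    return eq2_signal(c.x, kd_common, 10 ** theta[2], theta[0], theta[1]) - c.y
                res = least_squares(
                    resid,
                    [c.y.min(), c.y.max() - c.y.min(), np.log10(c.dt_hint)],
                    bounds=([-np.inf, -np.inf, -14], [np.inf, np.inf, -4]),
                )
                pooled += 2 * res.cost
            assert gfit.rss_ <= pooled + 1e-9

    def test_median_recovery_bias_under_five_percent(self):
        """Across seeds: median relative Kd bias < 5% at 2% noise."""
        from crafruk import simulate

        biases = []
        for seed in range(7):
            curves, _ = simulate.gen_titration(simulate.TitrationSimSpec(seed=seed))
            fit = fit_global(curves, n_starts=3)
            biases.append(abs(fit.kd_ - 2.0e-9) / 2.0e-9)
        assert np.median(biases) < 0.05


class TestBootstrap:
    def test_noiseless_interval_collapses(self, noiseless_curves):
        curves, truth, spec = noiseless_curves
        fit = fit_global(curves)
        lo, hi, _ = binding.bootstrap_ci(fit, curves, n_boot=60, seed=5)
        assert hi - lo < 1e-3 * fit.kd_

    def test_seeded_reproducibility(self, titration_set):
        curves, _ = titration_set
        fit = fit_global(curves)
        a = binding.bootstrap_ci(fit, curves, n_boot=60, seed=9)
        b = binding.bootstrap_ci(fit, curves, n_boot=60, seed=9)
        assert a[0] == b[0] and a[1] == b[1]

    def test_small_n_boot_warns(self, titration_set):
        curves, _ = titration_set
        fit = fit_global(curves)
        with pytest.warns(UserWarning, match="n_boot"):
            binding.bootstrap_ci(fit, curves, n_boot=10, seed=1)
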