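"""Pattern-search optimizer, objective plumbing, and block fits."""

import numpy as np
import pytest

from ermodel.calibration import (
    fit_block,
    hooke_jeeves,
    predict_competition,
    predict_saturation,
    sse_objective,
)
from ermodel.datasets import Dataset
from ermodel.params import default_params
from ermodel.synthetic import NoiseSpec, gen_reporter, gen_saturation

import pandas as pd


class TestHookeJeeves:
    def test_convex_1d(self):
        res = hooke_jeeves(lambda x: (x[0] - 3) ** 2, [0.0], tol=1e-8)
        assert res.x[0] == pytest.approx(3.0, abs=1e-6)
        assert res.converged

    def test_anisotropic_quadratic(self):
        f = lambda x: (x[0] - 1) ** 2 + 100 * (x[1] + 2) ** 2
        res = hooke_jeeves(f, [5.0, 5.0], tol=1e-8, max_iter=50_000)
        assert res.x == pytest.approx([1.0, -2.0], abs=1e-5)

    def test_rosenbrock(self):
        f = lambda x: (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2
        res = hooke_jeeves(f, [-1.2, 1.0], step=0.25, tol=1e-9,
                           max_iter=200_000)
        assert res.sse < 1e-6

    def test_never_worse_than_start_and_respects_bounds(self):
        f = lambda x: -x[0]  # unbounded below without the box
        res = hooke_jeeves(f, [0.5], bounds=[(0.0, 1.0)], tol=1e-8)
        assert res.sse <= -0.5
        assert 0.0 <= res.x[0] <= 1.0

    def test_failures_treated_as_rejected_moves(self):
        def f(x):
            if x[0] < 0:
                raise FloatingPointError("domain")
            return (x[0] - 0.1) ** 2
        res = hooke_jeeves(f, [1.0], tol=1e-8)
        assert res.x[0] == pytest.approx(0.1, abs=1e-6)
        assert res.eval_failures > 0


class TestObjective:
    def _ds(self, x, y):
        return Dataset("saturation", {"ER_t": 1.0},
                       pd.DataFrame({"x": x, "y": y}))

    def test_exact_model_gives_zero(self, K):
        x = np.geomspace(0.01, 10, 8)
        ds = self._ds(x, predict_saturation(K, 1.0, x))
        assert sse_objective(ds, lambda g: predict_saturation(K, 1.0, g)) == 0

    def test_constant_offset(self, K):
        x = np.geomspace(0.01, 10, 8)
        y = predict_saturation(K, 1.0, x)
        ds = self._ds(x, y + 0.5)
        assert sse_objective(ds, lambda g: predict_saturation(K, 1.0, g)) == \
            pytest.approx(8 * 0.25, rel=1e-9)

    def test_noise_floor_matches_chi_square_expectation(self, K, rng):
        x = np.geomspace(0.01, 30, 12)
        y = predict_saturation(K, 7.0, x)
        sigma = 0.02 * y.max()
        sses = []
        for _ in range(40):
            ds = self._ds(x, y + rng.normal(0, sigma, y.size))
            sses.append(sse_objective(ds, lambda g: predict_saturation(K, 7.0, g)))
        expect = x.size * sigma**2
        assert np.mean(sses) == pytest.approx(expect, rel=0.35)


class TestPredictors:
    def test_competition_free_point_is_100pct(self, K):
        out = predict_competition(K, 1.0, 1.0, [0.0, 1.0], "hormone-like")
        assert out[0] == pytest.approx(100.0)

    def test_equal_unlabelled_halves_labelled_share(self, K):
        """Pooling symmetry: at competitor == labelled concentration the
        labelled fraction of total hormone is exactly one half."""
        from ermodel.core import SystemTotals, solve_equilibrium, bound_hormone_metrics
        out = predict_competition(K, 1.0, 1.0, [1.0], "hormone-like")
        tot = SystemTotals(ER_t=1.0, H_t=2.0)
        er_b2, _ = bound_hormone_metrics(solve_equilibrium(K, tot), tot)
        tot0 = SystemTotals(ER_t=1.0, H_t=1.0)
        er_b0, _ = bound_hormone_metrics(solve_equilibrium(K, tot0), tot0)
        assert out[0] == pytest.approx(100.0 * (er_b2 / 2) / er_b0, rel=1e-9)

    def test_large_dose_limits(self, K):
        horm = predict_competition(K, 1.0, 1.0, [1e7], "hormone-like")
        inhib = predict_competition(K, 1.0, 1.0, [1e7], "inhibitor")
        assert horm[0] < 0.1              # label fully displaced
        assert 0.0 < inhib[0] < 20.0      # hormone-retaining floor

    def test_inhibitor_ic50_reflects_weaker_binding(self, K):
        """Tamoxifen (K9=30 nM monomer) displaces the label at much higher
        dose than unlabelled estradiol (K4=0.25 nM)."""
        grid = np.geomspace(0.01, 1e5, 60)

        def ic50(kind):
            y = predict_competition(K, 1.0, 1.0, grid, kind)
            return np.interp(-50.0, -y, grid)
        assert ic50("inhibitor") > 10 * ic50("hormone-like")


class TestFitBlock:
    def test_zero_free_parameters(self, K, params):
        x = np.geomspace(0.01, 10, 6)
        ds = Dataset("saturation", {"ER_t": 1.0},
                     pd.DataFrame({"x": x, "y": predict_saturation(K, 1.0, x)}))
        res = fit_block([ds], [], params)
        assert res.sse == 0 and res.iterations == 0 and res.converged

    def test_noiseless_recovery_is_exact(self, params):
        """Identifiable constants are recovered to <1% from clean curves
        when the optimizer starts off-truth."""
        data = gen_saturation(params, NoiseSpec(magnitude=0.0, seed=1))
        from ermodel.params import default_binding_constants
        start = params.__class__(
            default_binding_constants(K2=0.4, K4=0.1), params.rates, params.totals)
        res = fit_block(data, ["K2", "K4"], start, seed=3, n_starts=2,
                        tol=1e-4, max_iter=1500)
        assert res.params["K2"] == pytest.approx(0.2, rel=0.01)
        assert res.params["K4"] == pytest.approx(0.25, rel=0.01)

    def test_noisy_monomer_affinity_recovery(self, params):
        """At 2% assay noise, the monomer hormone affinity K4 (the constant
        the low-receptor curves pin down) is recovered well within 25% when
        curves of different amplitude are inverse-variance weighted."""
        data = gen_saturation(params, NoiseSpec("additive-gaussian", 0.02, seed=7))
        from ermodel.params import default_binding_constants
        start = params.__class__(
            default_binding_constants(K4=0.4), params.rates, params.totals)
        res = fit_block(data, ["K4"], start, seed=5, n_starts=2,
                        tol=1e-3, max_iter=300, weighted=True)
        assert res.params["K4"] == pytest.approx(0.25, rel=0.25)

    def test_reporter_scale_recovery(self, params):
        data = gen_reporter(params, NoiseSpec("multiplicative-lognormal", 0.05, 11),
                            H_levels=(0.0,), scale=3.0)
        from dataclasses import replace as drep
        start = params.__class__(
            params.binding, drep(params.rates, k_sr_i=0.05), params.totals)
        res = fit_block(data, ["k_sr_i", "scale"], start, seed=2, n_starts=2,
                        tol=1e-3, max_iter=400)
        assert res.params["k_sr_i"] == pytest.approx(0.02, rel=0.2)
        assert res.scale == pytest.approx(3.0, rel=0.2)

    def test_refit_from_solution_does_not_improve(self, params):
        data = gen_saturation(params, NoiseSpec(magnitude=0.0, seed=1),
                              ER_levels=(1.2,))
        res = fit_block(data, ["K4"], params, seed=0, n_starts=1, tol=1e-6)
        assert res.sse <= 1e-9  # started at the truth; nothing to improve

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(ValueError):
            fit_block([], ["K99"], params)
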