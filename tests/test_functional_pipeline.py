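import dataclasses

import numpy as np
import pandas as pd
import pytest

from funqee.fda_basis import build_bspline_basis, score_functional_covariate
from funqee.functional_pipeline import (
    BootstrapBand,
    bootstrap_functional_inference,
    bootstrap_scalar_inference,
    fit_fmem,
    fit_fqmem,
    functional_design,
    select_G_by_aic,
    significant_windows,
    stratified_resample_indices,
)
from funqee.mixed_models import fit_lmem
from funqee.synthetic_data import SimulationTruth, simulate_study


class TestComposition:
    def test_fmem_equals_engine_on_precomputed_scores(self, small_study):
        fit = fit_fmem(small_study, G=5)
        basis = build_bspline_basis(5, 3)
        y, X, clusters, names = functional_design(small_study, basis, ("age", "sex", "race", "desk"))
        direct = fit_lmem(y, X, clusters, names=names)
        np.testing.assert_array_equal(fit.engine_fit.beta_hat, direct.beta_hat)
        assert fit.engine_fit.loglik == direct.loglik

    def test_beta_curve_is_basis_times_gamma(self, small_study):
        fit = fit_fmem(small_study, G=6)
        basis = build_bspline_basis(6, 3)
        np.testing.assert_array_equal(
            fit.beta_curve.values,
            basis.design(small_study.grid.points) @ fit.gamma_hat,
        )

    def test_fqmem_determinism(self, small_study):
        a = fit_fqmem(small_study, 0.5, G=4)
        b = fit_fqmem(small_study, 0.5, G=4)
        np.testing.assert_array_equal(a.gamma_hat, b.gamma_hat)

    def test_fqmem_median_constant_curves(self, rng):
        # identical curves: the functional term is a constant, so the
        # fitted median at the common curve must track the sample median
        study = simulate_study(SimulationTruth(n=120, n_schools=3, seed=2))
        study = dataclasses.replace(
            study, curves=np.tile(study.curves[0], (study.n, 1))
        )
        fit = fit_fqmem(study, 0.5, G=4, covariates=())
        y = study.table["log_bmi"].to_numpy()
        fitted = fit.engine_fit.beta_hat[0] + score_functional_covariate(
            study.curves[0], study.grid, fit.basis
        ).values @ fit.gamma_hat
        assert abs(fitted - np.median(y)) < 0.02


class TestSelectG:
    def test_duplicates_collapse(self, small_study):
        best, table, fit = select_G_by_aic(small_study, "FMEM", G_range=(4, 4))
        assert best == 4
        assert len(table) == 1

    def test_default_range(self, small_study):
        best, table, fit = select_G_by_aic(small_study, "FMEM")
        assert sorted(table["G"]) == [4, 5, 6, 7]
        assert best in (4, 5, 6, 7)
        assert fit.basis.G == best
        ok = table[table["status"] == "ok"]
        assert ok.loc[ok["aic"].idxmin(), "G"] == best

    def test_fqmem_requires_tau(self, small_study):
        with pytest.raises(ValueError, match="tau"):
            select_G_by_aic(small_study, "FQMEM")

    def test_empty_range_rejected(self, small_study):
        with pytest.raises(ValueError, match="nonempty"):
            select_G_by_aic(small_study, "FMEM", G_range=())


class TestResampling:
    def test_sizes_preserved_per_school(self, small_study, rng):
        clusters = small_study.table["school_id"].to_numpy()
        idx = stratified_resample_indices(clusters, rng)
        orig = pd.Series(clusters).value_counts()
        new = pd.Series(clusters[idx]).value_counts()
        assert orig.equals(new)

    def test_permutation_reproduces_data(self, small_study, rng):
        clusters = small_study.table["school_id"].to_numpy()
        idx = stratified_resample_indices(clusters, rng, scheme="permutation")
        assert sorted(idx) == list(range(small_study.n))

    def test_invalid_scheme(self, small_study, rng):
        with pytest.raises(ValueError, match="scheme"):
            stratified_resample_indices(
                small_study.table["school_id"].to_numpy(), rng, scheme="wild"
            )


class TestBootstrap:
    def test_seed_reproducibility(self, small_study):
        fitter = lambda s: fit_fmem(s, G=4)
        b1 = bootstrap_functional_inference(
            small_study, fitter, B=60, rng=np.random.default_rng(3)
        )
        b2 = bootstrap_functional_inference(
            small_study, fitter, B=60, rng=np.random.default_rng(3)
        )
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_level_monotonicity(self, small_study):
        band = bootstrap_functional_inference(
            small_study, lambda s: fit_fmem(s, G=4), B=80,
            rng=np.random.default_rng(4),
        )
        lo90 = np.percentile(band.replicate_curves, 5.0, axis=0)
        hi90 = np.percentile(band.replicate_curves, 95.0, axis=0)
        assert np.all(lo90 >= band.lower - 1e-12)
        assert np.all(hi90 <= band.upper + 1e-12)

    def test_minimum_B(self, small_study):
        with pytest.raises(ValueError, match="B"):
            bootstrap_functional_inference(
                small_study, lambda s: fit_fmem(s, G=4), B=10
            )

    def test_permutation_scheme_gives_degenerate_band(self, small_study):
        band = bootstrap_functional_inference(
            small_study, lambda s: fit_fmem(s, G=4), B=60,
            resample_scheme="permutation", rng=np.random.default_rng(5),
        )
        np.testing.assert_allclose(band.upper - band.lower, 0.0, atol=1e-10)
        np.testing.assert_allclose(band.estimate, band.lower, atol=1e-10)

    def test_zero_noise_band_shrinks(self):
        # deterministic outcome: band width collapses with the noise
        truth = SimulationTruth(
            n=90, n_schools=3, seed=8, sigma2_school=0.0, sigma2_resid=1e-12
        )
        study = simulate_study(truth)
        band = bootstrap_functional_inference(
            study, lambda s: fit_fmem(s, G=4), B=60, rng=np.random.default_rng(6)
        )
        noisy = simulate_study(dataclasses.replace(truth, sigma2_resid=None, sigma2_school=None))
        band_noisy = bootstrap_functional_inference(
            noisy, lambda s: fit_fmem(s, G=4), B=60, rng=np.random.default_rng(6)
        )
        assert np.median(band.upper - band.lower) < 0.05 * np.median(
            band_noisy.upper - band_noisy.lower
        )

    def test_scalar_bootstrap_se_shapes(self, small_study):
        from funqee.mixed_models import DesignSpec, build_design

        spec = DesignSpec()
        _, _, _, names = build_design(small_study, spec)

        def fitter(s):
            y, X, cl, _ = build_design(s, spec)
            return fit_lmem(y, X, cl, names=names)

        se, p, n_failed = bootstrap_scalar_inference(
            small_study, fitter, B=60, rng=np.random.default_rng(7)
        )
        assert se.shape == (len(names),)
        assert np.all((p >= 0) & (p <= 1))
        assert n_failed == 0


class TestSignificantWindows:
    def _band(self, lower, upper, points=None):
        lower = np.asarray(lower, dtype=float)
        m = lower.size
        points = np.arange(1, m + 1) / m if points is None else points
        return BootstrapBand(
            points=points, estimate=(lower + upper) / 2, lower=lower,
            upper=np.asarray(upper, dtype=float), level=0.95, B=100,
            n_used=100, n_failed=0, param_names=[], param_estimates=np.array([]),
            param_se=np.array([]), param_p=np.array([]),
        )

    def test_single_window_hours_3_to_9(self):
        # positive lower bound on grid points 3..9 of 30 -> [0.1, 0.3]
        lower = np.full(30, -1.0)
        upper = np.full(30, 1.0)
        lower[2:9] = 0.01
        band = self._band(lower, upper)
        assert significant_windows(band) == [(pytest.approx(0.1), pytest.approx(0.3))]

    def test_straddling_everywhere_empty(self):
        band = self._band(np.full(30, -1.0), np.full(30, 1.0))
        assert significant_windows(band) == []

    def test_two_windows(self):
        lower = np.full(10, -1.0)
        upper = np.full(10, 1.0)
        lower[1:3] = 0.5  # points 2-3
        upper[7:9] = -0.5  # points 8-9 (negative effect)
        band = self._band(lower, upper)
        assert significant_windows(band) == [(0.2, 0.3), (0.8, 0.9)]

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            m = 12
            lower = rng.normal(size=m)
            upper = lower + np.abs(rng.normal(size=m)) + 1e-6
            band = self._band(lower, upper, points=np.arange(1, m + 1) / m)
            mask = (lower > 0) | (upper < 0)
            expected = []
            run = []
            for i, flag in enumerate(mask):
                if flag:
                    run.append(i)
                elif run:
                    expected.append((band.points[run[0]], band.points[run[-1]]))
                    run = []
            if run:
                expected.append((band.points[run[0]], band.points[run[-1]]))
            assert significant_windows(band) == [
                (pytest.approx(a), pytest.approx(b)) for a, b in expected
            ]
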