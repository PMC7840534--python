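import numpy as np
import pandas as pd
import pytest

import pollsel
from pollsel import selection as sel
from pollsel.exceptions import (
    BootstrapRetryError,
    ConfigurationError,
    DegenerateTraitError,
    NumericalError,
    ValidationError,
)


class TestStandardize:
    def test_symmetric_triple(self):
        tm = sel.standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert tm.z["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_direct_arithmetic(self):
        # mean 5, sample SD sqrt(13)
        tm = sel.standardize(pd.DataFrame({"x": [2.0, 4.0, 9.0]}))
        expected = (np.array([2.0, 4.0, 9.0]) - 5.0) / np.sqrt(13.0)
        assert tm.z["x"].tolist() == pytest.approx(expected.tolist(), abs=1e-4)
        assert tm.z["x"].tolist() == pytest.approx([-0.8321, -0.2774, 1.1094], abs=1e-4)

    def test_moments(self):
        rng = np.random.default_rng(0)
        tm = sel.standardize(pd.DataFrame(rng.normal(5, 3, size=(40, 3)),
                                          columns=list("abc")))
        np.testing.assert_allclose(tm.z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(tm.z.var(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateTraitError):
            sel.standardize(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            sel.standardize(pd.DataFrame({"x": [1.0, 2.0]}))


class TestSelectionDifferentials:
    def test_slope_by_hand(self):
        s, _ = sel.selection_differentials([-1.0, 0.0, 1.0], [0.5, 1.0, 1.5])
        assert s == pytest.approx(0.5)

    def test_constant_fitness(self):
        s, c = sel.selection_differentials([-1.0, 0.0, 1.0], [1.0, 1.0, 1.0])
        assert s == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_interpolation_and_doubling(self):
        # w = 1 - z + z^2... actually w=(1,0,1) on z=(-1,0,1): w = z^2 exactly
        z, w = [-1.0, 0.0, 1.0], [1.0, 0.0, 1.0]
        _, c_doubled = sel.selection_differentials(z, w, double_quadratic=True)
        _, c_raw = sel.selection_differentials(z, w, double_quadratic=False)
        assert c_raw == pytest.approx(1.0)
        assert c_doubled == pytest.approx(2.0)

    def test_s_equals_sample_covariance(self):
        rng = np.random.default_rng(1)
        z = sel.standardize(pd.DataFrame({"x": rng.normal(size=60)})).z["x"].to_numpy()
        w = pollsel.relative_fitness(rng.gamma(2.0, 1.0, size=60)).to_numpy()
        s, _ = sel.selection_differentials(z, w)
        assert s == pytest.approx(float(np.cov(w, z, ddof=1)[0, 1]), abs=1e-9)


class TestSelectionGradients:
    def test_exact_linear_surface(self):
        rng = np.random.default_rng(2)
        Z = sel.standardize(pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])).z
        w = 1.0 + 0.3 * Z["a"].to_numpy()
        beta, gii, gij = sel.selection_gradients(Z.to_numpy(), w, ["a", "b"])
        assert beta == pytest.approx([0.3, 0.0], abs=1e-9)
        assert gii == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_pure_interaction_on_factorial(self):
        # 3-level factorial: full second-order design has full rank
        grid = np.array([[z1, z2] for z1 in (-1.0, 0.0, 1.0) for z2 in (-1.0, 0.0, 1.0)])
        w = 1.0 + grid[:, 0] * grid[:, 1]
        beta, gii, gij = sel.selection_gradients(grid, w, ["a", "b"])
        assert gij[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert beta == pytest.approx([0.0, 0.0], abs=1e-9)
        assert gii == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_two_level_factorial_is_rank_deficient(self):
        # z in {-1, 1}: quadratic columns are constant, collinear with intercept
        grid = np.array([[z1, z2] for z1 in (-1.0, 1.0) for z2 in (-1.0, 1.0)])
        grid = np.tile(grid, (3, 1))
        w = 1.0 + grid[:, 0] * grid[:, 1]
        with pytest.raises(NumericalError, match=r"\^2"):
            sel.selection_gradients(grid, w, ["a", "b"])

    def test_single_trait_beta_equals_s(self):
        rng = np.random.default_rng(3)
        z = sel.standardize(pd.DataFrame({"x": rng.normal(size=40)})).z.to_numpy()
        w = pollsel.relative_fitness(rng.gamma(2.0, 1.0, size=40)).to_numpy()
        s, _ = sel.selection_differentials(z[:, 0], w)
        beta, _, _ = sel.selection_gradients(z, w, ["x"])
        assert beta[0] == pytest.approx(s, abs=1e-12)

    def test_orthogonal_traits_beta_equals_s(self):
        # exactly orthogonal standardized columns via QR
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        q = q - q.mean(axis=0)
        # re-orthogonalize after centering, then scale to unit sample variance
        q, _ = np.linalg.qr(q)
        q = q - q.mean(axis=0)
        Z = q / q.std(axis=0, ddof=1)
        w = pollsel.relative_fitness(rng.gamma(2.0, 1.0, size=30)).to_numpy()
        beta, _, _ = sel.selection_gradients(Z, w, list("abc"))
        for j in range(3):
            s, _ = sel.selection_differentials(Z[:, j], w)
            assert beta[j] == pytest.approx(s, abs=1e-6)

    def test_gamma_doubling_identity(self):
        rng = np.random.default_rng(5)
        Z = sel.standardize(pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))).z
        w = pollsel.relative_fitness(rng.gamma(2.0, 1.0, size=60)).to_numpy()
        _, gii2, gij2 = sel.selection_gradients(Z.to_numpy(), w, list("abc"), double_quadratic=True)
        _, gii1, gij1 = sel.selection_gradients(Z.to_numpy(), w, list("abc"), double_quadratic=False)
        np.testing.assert_allclose(gii2, 2.0 * gii1, atol=1e-12)
        np.testing.assert_allclose(gij2, gij1, atol=1e-12)  # cross products never doubled


class TestLogModelPvalues:
    @pytest.fixture()
    def fixture_data(self):
        rng = np.random.default_rng(6)
        Z = sel.standardize(pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))).z
        w = pollsel.relative_fitness(
            rng.gamma(2.0, 1.0, size=80) * np.exp(0.3 * Z["a"].to_numpy())).to_numpy()
        return Z, w

    def test_matches_statsmodels_oracle(self, fixture_data):
        sm = pytest.importorskip("statsmodels.api")
        Z, w = fixture_data
        pvals = sel.pvalues_log_model(Z.to_numpy(), w, offset=0.0, trait_names=list("abc"))
        y = np.log(w)
        # oracle: independent statsmodels fits of the same designs
        X = sm.add_constant(Z.to_numpy())
        fit = sm.OLS(y, X).fit()
        for j, name in enumerate("abc"):
            assert pvals[("beta", name, "")] == pytest.approx(fit.pvalues[1 + j], abs=1e-8)
        za = Z["a"].to_numpy()
        fit_s = sm.OLS(y, sm.add_constant(za)).fit()
        assert pvals[("S", "a", "")] == pytest.approx(fit_s.pvalues[1], abs=1e-8)
        fit_c = sm.OLS(y, sm.add_constant(np.column_stack([za, za**2]))).fit()
        assert pvals[("C_ii", "a", "")] == pytest.approx(fit_c.pvalues[2], abs=1e-8)
        from pollsel.selection import _full_design

        X_full, _, pairs = _full_design(Z.to_numpy(), list("abc"))
        fit_g = sm.OLS(y, X_full).fit()
        assert pvals[("gamma_ii", "a", "")] == pytest.approx(fit_g.pvalues[4], abs=1e-8)
        assert pvals[("gamma_ij", "a", "b")] == pytest.approx(fit_g.pvalues[7], abs=1e-8)

    def test_zero_fitness_with_zero_offset_rejected(self, fixture_data):
        Z, w = fixture_data
        w = w.copy()
        w[0] = 0.0
        with pytest.raises(ConfigurationError, match="bootstrap"):
            sel.pvalues_log_model(Z.to_numpy(), w, offset=0.0)

    def test_offset_rescues_zeros(self, fixture_data):
        Z, w = fixture_data
        w = w.copy()
        w[:5] = 0.0
        pvals = sel.pvalues_log_model(Z.to_numpy(), w, offset=1.0, trait_names=list("abc"))
        assert all(np.isfinite(v) for v in pvals.values())

    def test_estimates_invariant_to_offset(self, fixture_data):
        Z, w = fixture_data
        est = sel.estimate_coefficients(Z.to_numpy(), w, trait_names=list("abc"))
        # the offset enters only the p-value refits; estimates are untouched
        p1 = sel.pvalues_log_model(Z.to_numpy(), w, offset=1.0, trait_names=list("abc"))
        p0 = sel.pvalues_log_model(Z.to_numpy(), w, offset=0.0, trait_names=list("abc"))
        est_again = sel.estimate_coefficients(Z.to_numpy(), w, trait_names=list("abc"))
        assert est == est_again
        assert p1.keys() == p0.keys()


class TestBootstrap:
    def test_identical_rows_zero_width(self):
        data = np.ones((20, 1)) * 3.7
        cis = sel.bootstrap_cis(data, lambda d: {"mean": float(np.mean(d))},
                                sel.BootstrapSettings(replicates=50, seed=0))
        lo, hi = cis["mean"]
        assert lo == hi == pytest.approx(3.7)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(40, 1))
        est = lambda d: {"mean": float(np.mean(d))}
        a = sel.bootstrap_cis(data, est, sel.BootstrapSettings(replicates=100, seed=9))
        b = sel.bootstrap_cis(data, est, sel.BootstrapSettings(replicates=100, seed=9))
        assert a == b

    def test_retry_cap_exceeded(self):
        # full sample is valid, but half of all resamples collapse the trait;
        # with no retries allowed the cap trips almost surely over 50 replicates
        traits = np.array([[0.0], [1.0]])
        values = np.ones(2)
        est = sel.make_block_estimator(kinds=("S",), trait_names=["x"])
        with pytest.raises(BootstrapRetryError):
            sel.bootstrap_cis((traits, values), est,
                              sel.BootstrapSettings(replicates=50, seed=0, max_retries=0))

    def test_invalid_settings(self):
        with pytest.raises(ConfigurationError):
            sel.BootstrapSettings(replicates=0).validate()
        with pytest.raises(ConfigurationError):
            sel.BootstrapSettings(level=1.5).validate()


class TestSelectionReport:
    def test_structure(self, calibration_dataset, rates):
        plants, visits, _ = calibration_dataset
        report = sel.selection_report(
            plants, visits, rates, sel.BootstrapSettings(replicates=25, seed=3),
            log_model={"leafcutting": False})
        # 7 blocks x (6 traits x 4 per-trait kinds + 15 pairs)
        assert len(report) == 7 * (6 * 4 + 15)
        assert set(report["species"]) == {"all", "bumble", "honey", "leafcutting"}
        assert set(report["basis"]) == {"total", "visited", "tripped"}
        assert (report["ci_lower"] <= report["ci_upper"]).all()
        assert report.loc[report["species"] == "leafcutting", "p_log_model"].isna().all()
        assert report.loc[report["species"] == "all", "p_log_model"].notna().all()
        # unique coefficient identity per block
        key_cols = ["species", "basis", "coefficient_kind", "trait_1", "trait_2"]
        assert not report.duplicated(subset=key_cols).any()

    def test_deterministic(self, calibration_dataset, rates):
        plants, visits, _ = calibration_dataset
        kwargs = dict(bases=("visited",), include_total=False, kinds=("S", "beta"),
                      log_model={sp: False for sp in pollsel.SPECIES})
        a = sel.selection_report(plants, visits, rates,
                                 sel.BootstrapSettings(replicates=40, seed=5), **kwargs)
        b = sel.selection_report(plants, visits, rates,
                                 sel.BootstrapSettings(replicates=40, seed=5), **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_linear_surface_recovery(self):
        """beta recovers a constructed linear fitness surface to 1e-6."""
        rng = np.random.default_rng(11)
        plants = pollsel.generate_plants(pollsel.alfalfa_trait_model(), 100, rng)
        tm = sel.standardize(plants[list(pollsel.TRAIT_NAMES)])
        w = 1.0 + 0.45 * tm.z["stems_per_plant"].to_numpy()
        beta, _, _ = sel.selection_gradients(tm.z.to_numpy(), w, list(pollsel.TRAIT_NAMES))
        assert beta[0] == pytest.approx(0.45, abs=1e-6)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-6)
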