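"""Warped BLR normative models: conjugate limit, predictions, z-scores,
centiles, fit statistics, refitting."""

import numpy as np
import pytest
from scipy import stats

from nmqc.model import (
    FitConfig,
    compute_centiles,
    compute_zscores,
    fit_normative_model,
    fit_statistics,
    paired_ttest_pvalue,
    predict,
    refit_compare,
)
from nmqc.basis import build_basis
from nmqc.synthetic import ArtefactSpec, CohortSpec, generate_cohort
from nmqc.warp import WarpParams, warp_forward, warp_inverse


def test_identity_warp_fit_matches_conjugate_posterior(rng):
    # Gaussian linear data; the identity-warp fit must reproduce the
    # closed-form conjugate BLR posterior at its own (alpha, beta).
    n = 500
    ages = rng.uniform(45, 85, n)
    y = 0.02 * ages + rng.normal(0, 0.5, n)
    model = fit_normative_model(ages, y, FitConfig(warp="identity", seed=0))
    assert model.warp.is_identity
    Phi = model.basis.design_matrix(ages)
    A_ref = model.prior_precision * np.eye(Phi.shape[1]) + model.noise_precision * Phi.T @ Phi
    m_ref = model.noise_precision * np.linalg.solve(A_ref, Phi.T @ y)
    np.testing.assert_allclose(model.weight_precision, A_ref, atol=1e-6)
    np.testing.assert_allclose(model.weight_mean, m_ref, atol=1e-6)
    # and the noise level is close to the truth
    assert model.noise_variance == pytest.approx(0.25, rel=0.2)


def test_warp_parameter_recovery():
    rng = np.random.default_rng(2024)
    n = 5000
    ages = rng.uniform(45, 85, n)
    truth = WarpParams(a0=0.0, b0=1.0, epsilon=0.5, delta=1.3)
    latent = 0.5 * (ages - 65.0) / 20.0 + rng.normal(0, 1, n)
    y = warp_inverse(latent, truth)
    model = fit_normative_model(ages, y, FitConfig(seed=0))
    assert model.warp.epsilon == pytest.approx(0.5, abs=0.1)
    assert model.warp.delta == pytest.approx(1.3, abs=0.1)


def test_fit_is_deterministic(rng):
    ages = rng.uniform(45, 85, 400)
    y = 0.01 * ages + rng.normal(0, 0.3, 400) ** 3
    m1 = fit_normative_model(ages, y, FitConfig(seed=3))
    m2 = fit_normative_model(ages, y, FitConfig(seed=3))
    np.testing.assert_array_equal(m1.weight_mean, m2.weight_mean)
    assert m1.warp == m2.warp
    assert m1.noise_precision == m2.noise_precision


@pytest.mark.parametrize(
    "bad",
    [
        lambda rng: (np.full(20, 50.0), rng.normal(size=20)),  # constant ages
        lambda rng: (rng.uniform(45, 85, 5), rng.normal(size=5)),  # n < M + 2
        lambda rng: (rng.uniform(45, 85, 50), np.full(50, 1.3)),  # constant y
    ],
)
def test_degenerate_inputs_rejected(bad, rng):
    ages, y = bad(rng)
    with pytest.raises(ValueError):
        fit_normative_model(ages, y)


class TestPredict:
    def test_modelling_uncertainty_nonnegative(self, fitted_model):
        model, *_ = fitted_model
        pred = predict(model, np.linspace(45, 85, 100))
        assert np.all(pred.sigma_star2 >= 0)
        assert pred.sigma2 > 0

    def test_uncertainty_grows_toward_boundary(self, fitted_model):
        model, *_ = fitted_model
        pred = predict(model, np.array([65.0, 85.0]))
        assert pred.sigma_star2[1] > pred.sigma_star2[0]

    def test_prior_dominated_limit_shrinks_mean_to_zero(self, fitted_model):
        # with alpha -> inf the posterior mean weight vanishes, so the
        # latent predictive mean goes to zero
        model, ages, y, *_ = fitted_model
        import dataclasses

        Phi = model.basis.design_matrix(ages)
        alpha = 1e12
        A = alpha * np.eye(Phi.shape[1]) + model.noise_precision * Phi.T @ Phi
        m = model.noise_precision * np.linalg.solve(A, Phi.T @ warp_forward(y, model.warp))
        big = dataclasses.replace(model, weight_mean=m, weight_precision=A, prior_precision=alpha)
        pred = predict(big, np.linspace(46, 84, 50))
        assert np.max(np.abs(pred.latent_mean)) < 1e-6


class TestZScores:
    def test_zero_residual_gives_zero_z(self, fitted_model):
        model, *_ = fitted_model
        ages = np.array([60.0, 70.0])
        pred = predict(model, ages)
        y_on_curve = warp_inverse(pred.latent_mean, model.warp)
        z = compute_zscores(model, ages, y_on_curve)
        assert z == pytest.approx(np.zeros(2), abs=1e-8)

    def test_z_arithmetic(self):
        # residual 4, sigma2=3, sigma*2=1 -> z = 4 / sqrt(4) = 2
        assert 4.0 / np.sqrt(3.0 + 1.0) == pytest.approx(2.0)
        # the same arithmetic through the code path, with identity warp
        rng = np.random.default_rng(0)
        ages = rng.uniform(45, 85, 200)
        y = rng.normal(0, 1, 200)
        model = fit_normative_model(ages, y, FitConfig(warp="identity", seed=0))
        pred = predict(model, ages[:1])
        total = np.sqrt(pred.sigma2 + pred.sigma_star2[0])
        z = compute_zscores(model, ages[:1], pred.latent_mean[:1] + 4.0)
        assert z[0] == pytest.approx(4.0 / total, rel=1e-10)

    def test_heldout_z_standard_normal_on_matched_data(self):
        rng = np.random.default_rng(5)
        truth = WarpParams(a0=0.5, b0=0.04, epsilon=0.3, delta=0.9)
        def draw(n, seed):
            r = np.random.default_rng(seed)
            ages = r.uniform(45, 85, n)
            latent = -0.6 * (ages - 65) / 20 + r.normal(0, 1, n)
            return ages, warp_inverse(latent, truth)
        ages_tr, y_tr = draw(5000, 50)
        ages_te, y_te = draw(5000, 51)
        model = fit_normative_model(ages_tr, y_tr, FitConfig(seed=0))
        z = compute_zscores(model, ages_te, y_te)
        assert abs(z.mean()) < 0.05
        assert 0.95 < z.std() < 1.05


class TestCentiles:
    def test_median_is_inverse_warped_latent_mean(self, fitted_model):
        model, *_ = fitted_model
        ages = np.linspace(45, 85, 20)
        pred = predict(model, ages)
        c = compute_centiles(model, ages, levels=(50,))
        np.testing.assert_allclose(c[50], warp_inverse(pred.latent_mean, model.warp), rtol=1e-12)

    def test_centiles_non_crossing(self, fitted_model):
        model, *_ = fitted_model
        ages = np.linspace(45, 85, 50)
        c = compute_centiles(model, ages, levels=(1, 5, 25, 50, 75, 95, 99))
        qs = sorted(c)
        for lo, hi in zip(qs, qs[1:]):
            assert np.all(c[lo] < c[hi])

    def test_invalid_level_rejected(self, fitted_model):
        model, *_ = fitted_model
        with pytest.raises(ValueError):
            compute_centiles(model, np.array([60.0]), levels=(0,))
        with pytest.raises(ValueError):
            compute_centiles(model, np.array([60.0]), levels=(100,))

    def test_coverage_below_95th_centile(self, fitted_model):
        model, _, _, true_warp, _ = fitted_model
        r = np.random.default_rng(77)
        n = 10000
        ages = r.uniform(45, 85, n)
        latent = 0.04 * (ages - 65.0) / 10.0 + r.normal(0, 1, n)
        y = warp_inverse(latent, true_warp)
        c = compute_centiles(model, ages, levels=(95,))
        coverage = np.mean(y < c[95])
        assert coverage == pytest.approx(0.95, abs=0.01)


class TestFitStatistics:
    def test_noiseless_data_on_median_curve_gives_unit_ev(self, fitted_model):
        model, *_ = fitted_model
        ages = np.linspace(46, 84, 500)
        y = compute_centiles(model, ages, levels=(50,))[50]
        fs = fit_statistics(model, ages, y)
        assert fs.explained_variance == pytest.approx(1.0, abs=1e-9)

    def test_moments_match_hand_computed_formulas(self, fitted_model):
        model, ages, y, *_ = fitted_model
        fs = fit_statistics(model, ages[:200], y[:200])
        z = compute_zscores(model, ages[:200], y[:200])
        d = z - z.mean()
        m2, m3, m4 = (d**2).mean(), (d**3).mean(), (d**4).mean()
        assert fs.skew == pytest.approx(m3 / m2**1.5, abs=1e-12)
        assert fs.kurtosis == pytest.approx(m4 / m2**2 - 3.0, abs=1e-12)

    def test_standard_normal_z_moments(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(45, 85, 10000)
        y = rng.normal(0, 1, 10000)
        model = fit_normative_model(ages, y, FitConfig(warp="identity", seed=0))
        fs = fit_statistics(model, ages, y)
        assert fs.skew == pytest.approx(0.0, abs=0.08)
        assert fs.kurtosis == pytest.approx(0.0, abs=0.15)

    def test_zero_variance_rejected(self, fitted_model):
        model, *_ = fitted_model
        with pytest.raises(ValueError):
            fit_statistics(model, np.array([60.0, 61.0]), np.array([1.0, 1.0]))


class TestRefitCompare:
    def test_empty_mask_is_noop_with_nan_sentinel(self, fitted_model):
        model, ages, y, *_ = fitted_model
        refit, p = refit_compare(model, ages, y, np.zeros(len(ages), dtype=bool))
        assert np.isnan(p)
        np.testing.assert_allclose(refit.weight_mean, model.weight_mean, atol=1e-10)

    def test_paired_ttest_matches_textbook_formula(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.3, 0.5, 10)
        d = b - a
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert paired_ttest_pvalue(a, b) == pytest.approx(p_ref, abs=1e-10)

    def test_excluding_contamination_does_not_hurt_clean_fit(self):
        spec = CohortSpec(
            n_subjects=4000,
            seed=31,
            contamination=(ArtefactSpec("acquisition", 0.02, ("MD_fornix",), shift_sd=10.0),),
        )
        co = generate_cohort(spec)
        ages, y = co["age"].to_numpy(), co["MD_fornix"].to_numpy()
        mask = (co["true_category"] != "clean").to_numpy()
        m0 = fit_normative_model(ages, y, FitConfig(seed=0))
        m1, p = refit_compare(m0, ages, y, mask)
        clean = generate_cohort(CohortSpec(n_subjects=3000, seed=32))
        ev0 = fit_statistics(m0, clean["age"].to_numpy(), clean["MD_fornix"].to_numpy()).explained_variance
        ev1 = fit_statistics(m1, clean["age"].to_numpy(), clean["MD_fornix"].to_numpy()).explained_variance
        assert ev1 >= ev0
        assert 0 <= p <= 1  # z-scores genuinely change, so the test is defined

    def test_majority_exclusion_rejected(self, fitted_model):
        model, ages, y, *_ = fitted_model
        with pytest.raises(ValueError):
            refit_compare(model, ages, y, np.ones(len(ages), dtype=bool))


def test_model_json_roundtrip(tmp_path, fitted_model):
    model, ages, y, *_ = fitted_model
    path = tmp_path / "model.json"
    model.save(path)
    from nmqc.model import NormativeModel

    loaded = NormativeModel.load(path)
    np.testing.assert_allclose(loaded.weight_mean, model.weight_mean, rtol=1e-15)
    assert loaded.warp == model.warp
    z1 = compute_zscores(model, ages[:50], y[:50])
    z2 = compute_zscores(loaded, ages[:50], y[:50])
    np.testing.assert_allclose(z1, z2, rtol=1e-12)
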