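import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from dispersim.detectors import (
    DETECTORS,
    fit_nb_double_regression,
    gamlss_dispersion_lrt,
    levene_dispersion_test,
    mdseq_mean_dispersion_test,
    mdseq_outlier_trim,
    robust_dispersion_test,
)
from dispersim.detectors.levene import levene_statistic
from dispersim.detectors.mdseq import _fit_gene
from dispersim.detectors.robust import _fit_condition, tukey_biweight
from dispersim.preprocess import NormalizationFactors
from dispersim.simdata import CountDataset


def nb_ll(y, mu, phi):
    """Independent straight-line NB log-likelihood (oracle helper)."""
    r = 1.0 / phi
    return np.sum(
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def grid_ml(y, phi_grid=None):
    """2-D grid-search ML for an intercept-only NB fit (oracle).

    The ML mean of an intercept-only NB model is the sample mean for any
    fixed dispersion, so the profile over phi is one-dimensional.
    """
    mu = y.mean()
    if phi_grid is None:
        phi_grid = np.exp(np.linspace(np.log(1e-4), np.log(50), 6000))
    lls = np.array([nb_ll(y, mu, p) for p in phi_grid])
    i = int(np.argmax(lls))
    return mu, phi_grid[i], lls[i]


def two_group_dataset(y1, y2):
    y1, y2 = np.atleast_2d(y1), np.atleast_2d(y2)
    counts = np.hstack([y1, y2]).astype(int)
    n1, n2 = y1.shape[1], y2.shape[1]
    ds = CountDataset(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(n1 + n2)],
        condition=np.array([1] * n1 + [2] * n2),
    )
    lib = np.full(n1 + n2, 1.0)
    factors = NormalizationFactors(factors=np.ones(n1 + n2), library_sizes=lib)
    return ds, factors


class TestLevene:
    def test_identical_groups(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        W, p = levene_statistic(x, x.copy())
        assert W[0] == 0.0
        assert p[0] == 1.0

    def test_formula_against_scipy(self):
        g1 = np.array([1.0, 2.0, 3.0, 4.0])
        g2 = np.array([2.0, 4.0, 6.0, 8.0])
        W, p = levene_statistic(g1[None, :], g2[None, :])
        W_ref, p_ref = stats.levene(g1, g2, center="mean")
        assert W[0] == pytest.approx(W_ref, rel=1e-12)
        assert p[0] == pytest.approx(p_ref, rel=1e-12)

    def test_hand_step_through(self):
        # straight-line evaluation of the W formula on the same two groups
        g1 = np.array([1.0, 2.0, 3.0, 4.0])
        g2 = np.array([2.0, 4.0, 6.0, 8.0])
        z1 = np.abs(g1 - g1.mean())
        z2 = np.abs(g2 - g2.mean())
        zb1, zb2 = z1.mean(), z2.mean()
        zb = (z1.sum() + z2.sum()) / 8
        between = 4 * (zb1 - zb) ** 2 + 4 * (zb2 - zb) ** 2
        within = ((z1 - zb1) ** 2).sum() + ((z2 - zb2) ** 2).sum()
        expected = (8 - 2) / (2 - 1) * between / within
        W, _ = levene_statistic(g1[None, :], g2[None, :])
        assert W[0] == pytest.approx(expected, rel=1e-12)

    def test_location_invariance(self):
        g1 = np.array([[1.0, 2.0, 3.0, 4.0, 2.5]])
        g2 = np.array([[2.0, 4.0, 6.0, 8.0, 5.0]])
        _, p = levene_statistic(g1, g2)
        _, p_shift = levene_statistic(g1 + 7.0, g2)
        assert p[0] == pytest.approx(p_shift[0], rel=1e-12)

    def test_zero_deviation_both_groups(self):
        x = np.full((1, 4), 3.0)
        W, p = levene_statistic(x, x + 1.0)
        assert W[0] == 0.0 and p[0] == 1.0


class TestNBDoubleRegression:
    def test_grid_search_oracle(self, rng):
        y = rng.negative_binomial(5, 0.3, size=20)  # 20-observation toy vector
        X = np.ones((20, 1))
        fit = fit_nb_double_regression(y, X, X)
        mu_hat = np.exp(fit.coef_mean[0])
        phi_hat = np.exp(fit.coef_disp[0])
        mu_ref, phi_ref, ll_ref = grid_ml(y.astype(float))
        assert mu_hat == pytest.approx(mu_ref, rel=1e-4)
        assert phi_hat == pytest.approx(phi_ref, rel=2e-3)
        assert fit.loglik == pytest.approx(ll_ref, abs=1e-4)

    def test_constant_counts(self):
        y = np.full(30, 500)
        X = np.ones((30, 1))
        fit = fit_nb_double_regression(y, X, X)
        assert np.exp(fit.coef_mean[0]) == pytest.approx(500.0, rel=1e-4)
        assert np.exp(fit.coef_disp[0]) < 1e-4  # dispersion driven to the floor

    def test_offset_contract(self, rng):
        y = rng.negative_binomial(4, 0.2, size=40)
        X = np.ones((40, 1))
        base = fit_nb_double_regression(y, X, X)
        shifted = fit_nb_double_regression(y, X, X, offset=np.full(40, np.log(2.0)))
        assert np.exp(shifted.coef_mean[0]) == pytest.approx(
            np.exp(base.coef_mean[0]) / 2.0, rel=1e-5
        )
        assert shifted.coef_disp[0] == pytest.approx(base.coef_disp[0], abs=1e-4)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fit_nb_double_regression(np.array([-1, 2, 3]), np.ones((3, 1)), np.ones((3, 1)))


class TestGamlssLRT:
    def test_statistic_nonnegative(self, small_sim):
        res = gamlss_dispersion_lrt(small_sim["dataset"], small_sim["factors"])
        assert (res.stat_disp[res.converged] >= 0).all()
        assert (res.stat_mean[res.converged] >= 0).all()

    def test_lrt_matches_grid_search(self, rng):
        y1 = rng.negative_binomial(2, 0.05, size=30)
        y2 = rng.negative_binomial(10, 0.2, size=30)
        ds, factors = two_group_dataset(y1, y2)
        res = gamlss_dispersion_lrt(ds, factors)
        # oracle: group means are the ML means; profile phi on a fine grid
        y1f, y2f = y1.astype(float), y2.astype(float)
        _, _, ll1 = grid_ml(y1f)
        _, _, ll2 = grid_ml(y2f)
        ll_full = ll1 + ll2
        phi_grid = np.exp(np.linspace(np.log(1e-4), np.log(50), 6000))
        ll_red = max(
            nb_ll(y1f, y1f.mean(), p) + nb_ll(y2f, y2f.mean(), p) for p in phi_grid
        )
        expected = 2.0 * (ll_full - ll_red)
        assert res.stat_disp[0] == pytest.approx(expected, abs=5e-3)

    def test_type_one_error_calibration(self, rng):
        # equal dispersions in both groups: raw p_disp ~ uniform
        n, genes = 100, 400
        mu = rng.lognormal(5.0, 1.0, size=genes)
        phi = 0.2
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(genes, 2 * n))
        ds = CountDataset(
            counts=counts,
            gene_ids=[f"g{i}" for i in range(genes)],
            sample_ids=[f"s{j}" for j in range(2 * n)],
            condition=np.array([1] * n + [2] * n),
        )
        factors = NormalizationFactors(
            factors=np.ones(2 * n), library_sizes=np.full(2 * n, 1.0)
        )
        res = gamlss_dispersion_lrt(ds, factors)
        rate = float(np.mean(res.p_disp[res.converged] < 0.05))
        tol = 4 * np.sqrt(0.05 * 0.95 / genes)
        assert abs(rate - 0.05) < tol + 0.01


class TestMdseqTrim:
    def test_no_trim_when_clean(self):
        y = np.array([10.0, 12, 11, 9, 10, 13, 11, 12])
        cond = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        keep = mdseq_outlier_trim(y, np.ones(8), cond)
        assert keep.all()

    def test_extreme_value_removed(self):
        y = np.array([10.0, 12, 11, 9, 10, 13, 110, 12])
        cond = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        keep = mdseq_outlier_trim(y, np.ones(8), cond, k=5.0)
        assert not keep[6]
        assert keep.sum() == 7

    def test_min_retained_blocks_removal(self):
        y = np.array([10.0, 12, 11, 9, 10, 13, 110, 12])
        cond = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        keep = mdseq_outlier_trim(y, np.ones(8), cond, min_retained=4)
        assert keep.all()

    def test_threshold_arithmetic(self):
        # values 10x median in one condition exceed median + 5 * MAD
        vals = np.array([10.0, 11, 9, 100])
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(vals - med))
        assert vals[3] > med + 5 * mad


class TestMdseqDetector:
    def test_linear_parametrization_identity(self):
        # canonical NB with (mu, alpha): variance mu + alpha mu^2 = phi mu
        mu, alpha = 100.0, 0.5
        phi = 1.0 + alpha * mu
        assert mu + alpha * mu**2 == pytest.approx(phi * mu)
        assert phi == 51.0

    def test_poisson_boundary(self):
        # phi = 1 means variance equals mean
        mu, phi = 50.0, 1.0
        assert phi * mu == mu

    def test_wald_matches_numeric_hessian_oracle(self, rng):
        y1 = rng.negative_binomial(2, 0.02, size=25)
        y2 = rng.negative_binomial(2, 0.01, size=25)
        ds, factors = two_group_dataset(y1, y2)
        res = mdseq_mean_dispersion_test(ds, factors, trim_outliers=False)
        assert res.converged[0]

        # oracle: independent nll + full finite-difference Hessian at optimum
        y = ds.counts[0].astype(float)
        cond = (ds.condition == 2).astype(float)
        X = np.column_stack([np.ones(50), cond])

        def nll(theta):
            mu = np.exp(X @ theta[:2])
            phi = np.exp(X @ theta[2:])
            r = mu / (phi - 1.0)
            return -np.sum(
                gammaln(y + r)
                - gammaln(r)
                - gammaln(y + 1)
                + r * np.log(r / (r + mu))
                + y * np.log(mu / (r + mu))
            )

        g1m, g2m = ds.group_masks()
        params, cov, conv, boundary = _fit_gene(y, X, X, np.zeros(50), g1m, g2m)
        eps = 1e-4
        H = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                tpp = params.copy(); tpp[i] += eps; tpp[j] += eps
                tpm = params.copy(); tpm[i] += eps; tpm[j] -= eps
                tmp = params.copy(); tmp[i] -= eps; tmp[j] += eps
                tmm = params.copy(); tmm[i] -= eps; tmm[j] -= eps
                H[i, j] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (4 * eps**2)
        cov_ref = np.linalg.inv(0.5 * (H + H.T))
        z_ref = params[3] / np.sqrt(cov_ref[3, 3])
        assert res.stat_disp[0] == pytest.approx(z_ref, rel=5e-3)

    def test_threshold_one_is_plain_wald(self, rng):
        y1 = rng.negative_binomial(2, 0.02, size=20)
        y2 = rng.negative_binomial(2, 0.01, size=20)
        ds, factors = two_group_dataset(y1, y2)
        res = mdseq_mean_dispersion_test(ds, factors, trim_outliers=False)
        expected = 2 * stats.norm.sf(abs(res.stat_disp[0]))
        assert res.p_disp[0] == pytest.approx(expected, rel=1e-10)

    def test_threshold_raises_p(self, rng):
        y1 = rng.negative_binomial(2, 0.02, size=20)
        y2 = rng.negative_binomial(2, 0.01, size=20)
        ds, factors = two_group_dataset(y1, y2)
        base = mdseq_mean_dispersion_test(ds, factors, trim_outliers=False)
        thr = mdseq_mean_dispersion_test(
            ds, factors, trim_outliers=False, fc_threshold_disp=1.5
        )
        assert thr.p_disp[0] >= base.p_disp[0]

    def test_invalid_threshold_rejected(self, small_sim):
        with pytest.raises(ValueError):
            mdseq_mean_dispersion_test(
                small_sim["dataset"], small_sim["factors"], fc_threshold_mean=0.5
            )


class TestRobustDetector:
    def test_biweight_boundaries(self):
        assert tukey_biweight(0.0, c=4.0) == 1.0
        assert tukey_biweight(4.0, c=4.0) == 0.0
        assert tukey_biweight(-5.0, c=4.0) == 0.0
        assert 0 < tukey_biweight(2.0, c=4.0) < 1

    def test_clean_data_matches_ml(self, rng):
        mu, phi, n = 200.0, 0.3, 100
        r = 1.0 / phi
        y = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
        s = np.ones(n)
        _, lphi, _, ok = _fit_condition(y, s, c=4.0)
        assert ok
        _, phi_ml, _ = grid_ml(y)
        assert abs(lphi - np.log(phi_ml)) < 0.2

    def test_robust_to_single_outlier(self, rng):
        mu, phi, n = 150.0, 0.2, 60
        r = 1.0 / phi
        y = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
        s = np.ones(n)
        _, lphi_clean, _, _ = _fit_condition(y, s, c=4.0)
        _, phi_ml_clean, _ = grid_ml(y)
        y_cont = y.copy()
        y_cont[0] *= 10
        _, lphi_cont, _, _ = _fit_condition(y_cont, s, c=4.0)
        _, phi_ml_cont, _ = grid_ml(y_cont)
        shift_robust = abs(lphi_cont - lphi_clean)
        shift_ml = abs(np.log(phi_ml_cont) - np.log(phi_ml_clean))
        assert shift_robust < shift_ml

    def test_too_few_samples_rejected(self):
        ds, factors = two_group_dataset(np.array([[1, 2, 3]]), np.array([[1, 2, 3]]))
        with pytest.raises(ValueError, match="4 samples"):
            robust_dispersion_test(ds, factors)


class TestLabelSwapAntisymmetry:
    @pytest.mark.parametrize("name", ["levene", "mdseq", "robust", "gamlss"])
    def test_swap_negates_disp_fc(self, small_sim, name):
        ds = small_sim["dataset"]
        factors = small_sim["factors"]
        sub = ds.subset_genes(np.arange(25))
        swapped = CountDataset(
            counts=sub.counts,
            gene_ids=list(sub.gene_ids),
            sample_ids=list(sub.sample_ids),
            condition=np.where(sub.condition == 1, 2, 1),
        )
        res = DETECTORS[name](sub, factors)
        res_sw = DETECTORS[name](swapped, factors)
        ok = res.converged & res_sw.converged
        assert ok.mean() > 0.8
        np.testing.assert_allclose(
            res_sw.log2_disp_fc[ok], -res.log2_disp_fc[ok], atol=5e-2
        )
        np.testing.assert_allclose(res_sw.p_disp[ok], res.p_disp[ok], atol=5e-2)
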