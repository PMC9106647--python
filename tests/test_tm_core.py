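import numpy as np
import pytest
from scipy.special import logit as logit_fn

from anchortm.basis import BasisSpec, default_support
from anchortm.links import LINK_NAMES, make_link
from anchortm.tm_core import (
    CensoredResponse,
    ResponseData,
    TransformationModel,
    fit_mle,
    log_likelihood,
    martingale_residuals,
    model_preset,
    predict_cdf,
    predict_quantile,
    read_data,
    score_residual,
    score_residuals,
)
from conftest import tm_coefficients


@pytest.fixture
def bernstein_model():
    basis = BasisSpec("bernstein", order=4, support=(-2.0, 3.0))
    theta = np.array([-2.0, -1.0, 0.3, 1.2, 2.5])
    return TransformationModel(make_link("probit"), basis, theta, np.array([0.4, -0.7]))


class TestCensoredResponse:
    def test_exact_requires_equal_bounds(self):
        with pytest.raises(ValueError):
            CensoredResponse(0.0, 1.0, "exact")

    def test_interval_ordering(self):
        with pytest.raises(ValueError):
            CensoredResponse.interval(2.0, 1.0)

    def test_constructors(self):
        r = CensoredResponse.right(3.0)
        assert r.lower == 3.0 and r.upper == np.inf
        r = CensoredResponse.left(3.0)
        assert r.lower == -np.inf and r.upper == 3.0

    def test_unknown_tag(self):
        with pytest.raises(ValueError, match="tag"):
            CensoredResponse(0.0, 0.0, "middle")

    def test_response_data_no_mixing(self):
        with pytest.raises(ValueError, match="mix"):
            ResponseData.from_responses(
                [CensoredResponse.ordinal(1), CensoredResponse.exact(0.0)]
            )


class TestLogLikelihood:
    def test_lm_exact_at_zero(self):
        # standard normal density at 0: log phi(0) = -0.5 log(2 pi)
        link, basis = model_preset("lm", support=(-5.0, 5.0))
        model = TransformationModel(link, basis, np.array([0.0, 1.0]), np.zeros(1))
        ll = log_likelihood(model, CensoredResponse.exact(0.0), np.array([0.0]))
        assert ll == pytest.approx(-0.9189385332046727, abs=1e-9)

    def test_uninformative_interval_is_zero(self, bernstein_model):
        r = CensoredResponse(-np.inf, np.inf, "interval")
        ll = log_likelihood(bernstein_model, r, np.array([0.1, 0.2]))
        assert ll == pytest.approx(0.0)

    def test_right_censored_at_minus_inf_is_zero(self, bernstein_model):
        r = CensoredResponse(-np.inf, np.inf, "right")
        assert log_likelihood(bernstein_model, r, np.zeros(2)) == pytest.approx(0.0)

    def test_dimension_mismatch(self, bernstein_model):
        with pytest.raises(ValueError, match="covariate"):
            log_likelihood(bernstein_model, CensoredResponse.exact(0.0), np.zeros(5))

    def test_exact_is_limit_of_shrinking_interval(self, bernstein_model):
        # interval log-prob minus log(width) -> exact contribution
        x = np.array([0.3, -0.2])
        y, eps = 0.7, 1e-6
        exact = log_likelihood(bernstein_model, CensoredResponse.exact(y), x)
        interval = log_likelihood(bernstein_model, CensoredResponse.interval(y - eps, y), x)
        assert interval - np.log(eps) == pytest.approx(exact, abs=1e-3)

    @pytest.mark.parametrize("link_name", LINK_NAMES)
    def test_censored_cases_match_closed_form(self, link_name, bernstein_model):
        link = make_link(link_name)
        model = TransformationModel(link, bernstein_model.basis, bernstein_model.theta,
                                    bernstein_model.beta)
        x = np.array([0.5, 0.1])
        u = lambda y: float(model.transformation(y, x)[0])
        assert log_likelihood(model, CensoredResponse.left(1.0), x) == pytest.approx(
            np.log(link.cdf(u(1.0)))
        )
        assert log_likelihood(model, CensoredResponse.right(0.0), x) == pytest.approx(
            np.log(link.sf(u(0.0)))
        )
        assert log_likelihood(model, CensoredResponse.interval(-0.5, 1.5), x) == pytest.approx(
            np.log(link.cdf(u(1.5)) - link.cdf(u(-0.5)))
        )


def _augmented_ll(model, resp, x, alpha):
    """Log-likelihood with transformation h - alpha (extra intercept)."""
    theta = model.theta - alpha if model.basis.kind != "linear" else np.array(
        [model.theta[0] - alpha, model.theta[1]]
    )
    shifted = TransformationModel(model.link, model.basis, theta, model.beta)
    return log_likelihood(shifted, resp, x)


class TestScoreResiduals:
    @pytest.mark.parametrize("link_name", LINK_NAMES)
    @pytest.mark.parametrize(
        "resp",
        [
            CensoredResponse.exact(0.5),
            CensoredResponse.left(0.7),
            CensoredResponse.right(-0.4),
            CensoredResponse.interval(-0.5, 1.4),
        ],
        ids=["exact", "left", "right", "interval"],
    )
    def test_matches_fd_of_augmented_likelihood(self, link_name, resp, bernstein_model):
        model = TransformationModel(
            make_link(link_name), bernstein_model.basis, bernstein_model.theta, bernstein_model.beta
        )
        x = np.array([0.3, -1.2])
        r = score_residual(model, resp, x)
        eps = 1e-5
        fd = (_augmented_ll(model, resp, x, eps) - _augmented_ll(model, resp, x, -eps)) / (2 * eps)
        assert r == pytest.approx(fd, abs=1e-6)

    def test_probit_exact_zero_at_zero(self):
        link, basis = model_preset("lm", support=(-5, 5))
        model = TransformationModel(link, basis, np.array([0.0, 1.0]), np.zeros(1))
        assert score_residual(model, CensoredResponse.exact(0.0), np.zeros(1)) == pytest.approx(0.0)

    def test_lm_residuals_are_scaled_ls_residuals(self, lm_setup):
        fit = fit_mle("probit", lm_setup["basis"], lm_setup["X"], lm_setup["data"])
        b0, slopes, sigma = tm_coefficients(fit.model)
        r = score_residuals(fit.model, lm_setup["X"], lm_setup["data"])
        expected = (lm_setup["y"] - b0 - lm_setup["X"] @ slopes) / sigma
        np.testing.assert_allclose(r, expected, atol=1e-8)

    def test_mev_exact_and_right_are_martingale_residuals(self):
        # exact: Lambda - 1; right-censored: Lambda (score-residual convention)
        basis = BasisSpec("bernstein", order=4, support=(0.0, 5.0))
        theta = np.array([-3.0, -1.5, -0.5, 0.5, 1.0])
        model = TransformationModel(make_link("mev"), basis, theta, np.zeros(0))
        y = 2.0
        Lam = np.exp(float(model.transformation(y)[0]))
        assert score_residual(model, CensoredResponse.exact(y)) == pytest.approx(Lam - 1.0)
        assert score_residual(model, CensoredResponse.right(y)) == pytest.approx(Lam)
        data = ResponseData.from_responses(
            [CensoredResponse.exact(y), CensoredResponse.right(y)]
        )
        np.testing.assert_allclose(
            martingale_residuals(model, None, data), [1.0 - Lam, -Lam], atol=1e-12
        )

    def test_martingale_needs_mev(self, bernstein_model):
        with pytest.raises(ValueError, match="mev"):
            martingale_residuals(bernstein_model, None, ResponseData.from_exact([0.5]))

    def test_degenerate_interval_errors(self, bernstein_model):
        x = np.zeros(2)
        with pytest.raises(FloatingPointError, match="zero-probability"):
            # both bounds clamp far into the same tail -> zero mass
            model = TransformationModel(
                bernstein_model.link, bernstein_model.basis,
                bernstein_model.theta + 50.0, bernstein_model.beta,
            )
            score_residual(model, CensoredResponse.interval(-1.9, -1.8), x)


class TestFitMle:
    def test_lm_equals_ols(self, lm_setup):
        y, X = lm_setup["y"], lm_setup["X"]
        fit = fit_mle("probit", lm_setup["basis"], X, lm_setup["data"])
        assert fit.converged
        Z = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(Z, y, rcond=None)[0]
        resid = y - Z @ ols
        sigma2_mle = resid @ resid / len(y)  # divisor n
        b0, slopes, sigma = tm_coefficients(fit.model)
        np.testing.assert_allclose(b0, ols[0], rtol=1e-6)
        np.testing.assert_allclose(slopes, ols[1:], rtol=1e-6)
        np.testing.assert_allclose(sigma**2, sigma2_mle, rtol=1e-6)

    def test_ordinal_unconditional_matches_empirical_quantiles(self, rng):
        k = rng.integers(1, 6, size=500)
        link, basis = model_preset("o-logit", n_classes=5)
        fit = fit_mle(link, basis, None, ResponseData.from_ordinal(k))
        cum = np.cumsum(np.bincount(k, minlength=6)[1:5]) / k.size
        np.testing.assert_allclose(fit.model.theta, logit_fn(cum), atol=1e-6)

    def test_all_uninformative_errors(self):
        data = ResponseData.from_responses(
            [CensoredResponse(-np.inf, np.inf, "interval") for _ in range(10)]
        )
        with pytest.raises(ValueError, match="constant"):
            fit_mle("probit", BasisSpec("linear", support=(0, 1)), None, data)

    def test_too_few_observations(self):
        data = ResponseData.from_exact([1.0, 2.0])
        with pytest.raises(ValueError, match="observations"):
            fit_mle("probit", BasisSpec("bernstein", order=6, support=(0, 3)), None, data)

    def test_score_residuals_sum_to_zero_at_mle(self, lm_setup):
        fit = fit_mle("probit", lm_setup["basis"], lm_setup["X"], lm_setup["data"])
        r = score_residuals(fit.model, lm_setup["X"], lm_setup["data"])
        assert abs(r.mean()) < 1e-6

    def test_bernstein_residuals_sum_to_zero_at_mle(self, rng):
        y = rng.gamma(2.0, 1.0, size=300)
        X = rng.normal(size=(300, 2))
        y = y + 0.5 * X[:, 0]
        data = ResponseData.from_exact(y)
        basis = BasisSpec("bernstein", order=5, support=default_support(y))
        fit = fit_mle("logit", basis, X, data)
        assert fit.converged
        r = score_residuals(fit.model, X, data)
        assert abs(r.mean()) < 1e-5

    def test_censored_fit_runs_and_converges(self, rng):
        y = rng.normal(size=300)
        X = rng.normal(size=(300, 2))
        y = y + X @ np.array([1.0, -0.5])
        cens = np.quantile(y, 0.7)
        lo = np.where(y > cens, cens, y)
        hi = np.where(y > cens, np.inf, y)
        tags = np.where(y > cens, "right", "exact").astype(object)
        data = ResponseData(lo, hi, tags)
        basis = BasisSpec("bernstein", order=5, support=default_support(lo[np.isfinite(lo)]))
        fit = fit_mle("mev", basis, X, data)
        assert fit.converged and np.isfinite(fit.nll)


class TestPrediction:
    def test_cdf_quantile_round_trip(self, lm_setup):
        fit = fit_mle("probit", lm_setup["basis"], lm_setup["X"], lm_setup["data"])
        x = lm_setup["X"][3]
        for p in (0.1, 0.5, 0.9):
            q = predict_quantile(fit.model, p, x)
            F = predict_cdf(fit.model, np.array([q]), x)[0]
            assert F == pytest.approx(p, abs=1e-6)

    def test_lm_median_is_mean(self, lm_setup):
        fit = fit_mle("probit", lm_setup["basis"], lm_setup["X"], lm_setup["data"])
        b0, slopes, _ = tm_coefficients(fit.model)
        x = lm_setup["X"][0]
        assert predict_quantile(fit.model, 0.5, x) == pytest.approx(b0 + x @ slopes, abs=1e-6)

    def test_cdf_matches_known_composition(self):
        # c-probit with known theta: CDF must equal F_Z(h) exactly
        basis = BasisSpec("bernstein", order=6, support=(-1.0, 1.0))
        theta = np.linspace(-2, 2, 7)
        model = TransformationModel(make_link("probit"), basis, theta, np.zeros(0))
        y = np.linspace(-0.99, 0.99, 101)
        from anchortm.basis import evaluate_basis_matrix

        expected = make_link("probit").cdf(evaluate_basis_matrix(basis, y) @ theta)
        np.testing.assert_allclose(predict_cdf(model, y), expected, atol=1e-8)

    def test_cdf_nondecreasing(self, bernstein_model):
        F = predict_cdf(bernstein_model, np.linspace(-2, 3, 500), np.array([0.2, 0.1]))
        assert np.all(np.diff(F) >= -1e-12)

    def test_quantile_outside_support_warns(self):
        basis = BasisSpec("bernstein", order=3, support=(0.0, 1.0))
        model = TransformationModel(
            make_link("probit"), basis, np.array([2.0, 2.5, 3.0, 3.5]), np.zeros(0)
        )
        with pytest.warns(RuntimeWarning, match="boundary"):
            assert predict_quantile(model, 0.5, None) == 0.0

    def test_invalid_p(self, bernstein_model):
        with pytest.raises(ValueError):
            predict_quantile(bernstein_model, 1.5, np.zeros(2))

    def test_ordinal_quantile(self):
        link, basis = model_preset("o-logit", n_classes=4)
        model = TransformationModel(link, basis, np.array([-1.0, 0.0, 1.0]), np.zeros(0))
        assert predict_quantile(model, 0.5, None) == 2
        assert predict_quantile(model, 0.99, None) == 4


class TestReadData:
    def test_round_trip_censored(self, tmp_path):
        csv = (
            "response_lower,response_upper,censoring,x1,a1\n"
            "1.0,1.0,exact,0.5,1\n"
            ",2.0,left,0.1,0\n"
            "3.0,,right,-0.2,1\n"
            "0.5,1.5,interval,0.0,0\n"
        )
        path = tmp_path / "data.csv"
        path.write_text(csv)
        data, X, A = read_data(str(path), covariates=["x1"], anchors=["a1"])
        assert list(data.tags) == ["exact", "left", "right", "interval"]
        assert data.lower[1] == -np.inf and data.upper[2] == np.inf
        assert X.shape == (4, 1) and A.shape == (4, 1)

    def test_ordinal_column(self, tmp_path):
        path = tmp_path / "ord.csv"
        path.write_text("response_class,x1\n1,0.0\n3,0.5\n2,1.0\n")
        data, X, A = read_data(str(path), covariates=["x1"], response_class="response_class")
        assert data.is_ordinal
        np.testing.assert_array_equal(data.class_index, [1, 3, 2])

    def test_bad_tag(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("response_lower,response_upper,censoring\n1.0,1.0,weird\n")
        with pytest.raises(ValueError, match="weird"):
            read_data(str(path))


class TestRecoveryProperty:
    def test_cprobit_recovers_beta_within_3se(self):
        """Unconfounded c-probit simulation: beta within 3 SE in >= 95% of replicates."""
        from anchortm.basis import evaluate_basis_matrix
        from anchortm.sem_sim import _invert_bernstein

        n_rep, hits = 40, 0
        beta_true = np.array([0.8])
        basis = BasisSpec("bernstein", order=6, support=(-6.0, 6.0))
        theta_true = np.linspace(-3.0, 3.0, 7) + np.array([0, 0.2, 0.1, 0, 0.3, 0.1, 0])
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(500, 1))
            t = rng.normal(size=500) + X[:, 0] * beta_true[0]
            bad = (t <= theta_true[0]) | (t >= theta_true[-1])
            while np.any(bad):  # redraw rare out-of-range latents
                X[bad] = rng.normal(size=(int(bad.sum()), 1))
                t[bad] = rng.normal(size=int(bad.sum())) + X[bad, 0] * beta_true[0]
                bad = (t <= theta_true[0]) | (t >= theta_true[-1])
            y = _invert_bernstein(basis, theta_true, t)
            data = ResponseData.from_exact(y)
            fit = fit_mle("probit", basis, X, data)
            se = _beta_se(fit, X, data)
            hits += abs(fit.model.beta[0] - beta_true[0]) <= 3 * se
        assert hits >= int(0.9 * n_rep)


def _beta_se(fit, X, data):
    """Standard error of beta from the observed information (FD of the gradient)."""
    from anchortm.tm_core import LikelihoodParts, _nll_and_grad_free

    basis = fit.model.basis
    parts = LikelihoodParts(basis, X, data)
    n = len(data)
    z = fit.free_params  # unconstrained parametrization at the optimum
    k = z.size
    H = np.zeros((k, k))
    eps = 1e-5
    for j in range(k):
        e = np.zeros(k)
        e[j] = eps
        gp = _nll_and_grad_free(z + e, fit.model.link, basis, parts, n)[1]
        gm = _nll_and_grad_free(z - e, fit.model.link, basis, parts, n)[1]
        H[:, j] = (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T) * n  # total-likelihood information
    cov = np.linalg.inv(H)
    return float(np.sqrt(cov[-1, -1]))
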