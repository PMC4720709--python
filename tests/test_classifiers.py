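"""QDA, plug-in Bayes, and OBC discriminants."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import invwishart, multivariate_t

import sdebayes as sb
from sdebayes.classifiers import OBCClassParams, build_qda_from_moments
from sdebayes.exceptions import InvalidInputError, NumericalError


def _random_niw(rng, d, kappa_extra=8.0):
    A = rng.normal(size=(d, d))
    Psi = A @ A.T + d * np.eye(d)
    return sb.NIWParams(m=rng.normal(size=d), Psi=Psi,
                        nu=float(rng.uniform(1, 10)),
                        kappa=float(d + 1 + rng.uniform(1, kappa_extra)))


class TestQDADiscriminant:
    def test_fully_symmetric_model_is_zero(self):
        m = np.zeros(2)
        clf = build_qda_from_moments(m, np.eye(2), m, np.eye(2), alpha1=0.5)
        x = np.array([[0.3, -1.2], [5.0, 5.0]])
        np.testing.assert_allclose(clf.discriminant(x), 0.0, atol=1e-12)

    def test_prior_odds_term_alone_survives_equal_classes(self):
        m = np.ones(3)
        clf = build_qda_from_moments(m, np.eye(3), m, np.eye(3), alpha1=0.25)
        psi = clf.discriminant(np.array([[0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(psi, -np.log(1.0 / 3.0))
        assert clf.classify(np.zeros(3)) == 0

    def test_one_dimensional_midpoint_is_the_boundary(self):
        clf = build_qda_from_moments([0.0], [[1.0]], [1.0], [[1.0]], alpha1=0.5)
        assert abs(clf.discriminant(np.array([0.5]))) < 1e-12
        # strict > is required for class 0, so the boundary point goes to 1
        assert clf.classify(np.array([0.5])) == 1
        assert clf.classify(np.array([0.49])) == 0
        assert clf.classify(np.array([0.51])) == 1

    def test_matches_gaussian_log_odds_oracle(self):
        rng = np.random.default_rng(1)
        from scipy.stats import multivariate_normal

        for _ in range(5):
            d = 3
            A0, A1 = rng.normal(size=(2, d, d))
            P0 = A0 @ A0.T + d * np.eye(d)
            P1 = A1 @ A1.T + d * np.eye(d)
            m0, m1 = rng.normal(size=(2, d))
            a1 = float(rng.uniform(0.2, 0.8))
            clf = build_qda_from_moments(m0, P0, m1, P1, alpha1=a1)
            X = rng.normal(size=(10, d))
            oracle = (
                np.log(1 - a1) + multivariate_normal(m0, P0).logpdf(X)
                - np.log(a1) - multivariate_normal(m1, P1).logpdf(X)
            )
            np.testing.assert_allclose(clf.discriminant(X), oracle, rtol=1e-9)

    def test_non_pd_covariance_rejected_at_build_time(self):
        with pytest.raises(NumericalError):
            build_qda_from_moments([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]],
                                   [1.0, 1.0], np.eye(2), alpha1=0.5)


class TestEffectiveDensity:
    def test_at_location_only_normalizer_remains(self):
        params = OBCClassParams(m_star=np.array([1.0, 2.0]), Pi=2.0 * np.eye(2), k=5.0)
        from scipy.special import gammaln

        expected = (gammaln(3.5) - gammaln(2.5) - np.log(5 * np.pi)
                    - 0.5 * np.log(4.0))
        got = sb.obc_log_effective_density(params, np.array([1.0, 2.0]))
        np.testing.assert_allclose(got, expected)

    def test_matches_scipy_multivariate_t(self):
        rng = np.random.default_rng(2)
        for d in (1, 3):
            A = rng.normal(size=(d, d))
            Pi = A @ A.T + d * np.eye(d)
            m = rng.normal(size=d)
            k = float(rng.uniform(2, 40))
            params = OBCClassParams(m_star=m, Pi=Pi, k=k)
            X = rng.normal(size=(20, d))
            np.testing.assert_allclose(
                sb.obc_log_effective_density(params, X),
                multivariate_t(loc=m, shape=Pi, df=k).logpdf(X),
                rtol=1e-10,
            )

    def test_integrates_to_one_in_one_dimension(self):
        params = OBCClassParams(m_star=np.array([0.5]), Pi=np.array([[1.7]]), k=4.0)
        total, _ = quad(
            lambda x: np.exp(sb.obc_log_effective_density(params, np.array([[x]]))[0]),
            -np.inf, np.inf, limit=200,
        )
        assert abs(total - 1.0) < 1e-6

    def test_gaussian_limit_at_large_dof(self):
        from scipy.stats import norm

        k = 1e6
        params = OBCClassParams(m_star=np.array([0.0]), Pi=np.array([[1.0]]), k=k)
        xs = np.linspace(-3, 3, 13).reshape(-1, 1)
        got = sb.obc_log_effective_density(params, xs)
        np.testing.assert_allclose(got, norm.logpdf(xs[:, 0]), atol=1e-3)


class TestOBC:
    def test_identical_posteriors_tie_everywhere_to_class_zero(self):
        rng = np.random.default_rng(3)
        post = _random_niw(rng, 2)
        clf = sb.build_obc(post, post, alpha1=0.5)
        X = rng.normal(size=(50, 2))
        assert np.all(clf.classify(X) == 0)

    def test_effective_parameters_follow_posterior(self):
        post = sb.NIWParams(m=np.arange(2.0), Psi=np.eye(2), nu=4.0, kappa=7.0)
        clf = sb.build_obc(post, post, alpha1=0.5)
        k = 7.0 - 2 + 1
        np.testing.assert_allclose(clf.class0.k, k)
        np.testing.assert_allclose(clf.class0.Pi, (5.0 / (k * 4.0)) * np.eye(2))

    def test_nonpositive_dof_rejected(self):
        # NIW propriety (kappa > Np - 1) already implies k > 0, so the guard
        # sits on the effective-parameter bundle itself
        with pytest.raises(InvalidInputError):
            OBCClassParams(m_star=np.zeros(2), Pi=np.eye(2), k=0.0)

    def test_prior_dominance_limit_equals_qda_with_prior_moments(self):
        """With nu = kappa - Np -> infinity the effective t densities
        collapse onto the prior-implied Gaussians: OBC and QDA decisions
        coincide."""
        d = 4
        rng = np.random.default_rng(4)
        A0, A1 = rng.normal(size=(2, d, d))
        P0 = A0 @ A0.T + d * np.eye(d)
        P1 = A1 @ A1.T + d * np.eye(d)
        m0, m1 = rng.normal(size=(2, d))
        big = 1e6
        pri0 = sb.NIWParams(m=m0, Psi=(big - 1) * P0, nu=big, kappa=d + big)
        pri1 = sb.NIWParams(m=m1, Psi=(big - 1) * P1, nu=big, kappa=d + big)
        obc = sb.build_obc(pri0, pri1, alpha1=0.4)
        qda = build_qda_from_moments(m0, P0, m1, P1, alpha1=0.4)
        X = rng.normal(size=(200, d)) * 2
        np.testing.assert_array_equal(obc.classify(X), qda.classify(X))

    def test_matches_posterior_predictive_oracle_on_small_instances(self):
        """OBC labels agree with brute-force Monte-Carlo posterior-predictive
        comparison (draw (mu, Sigma) from each NIW posterior, average the
        Gaussian densities) whenever the oracle is conclusive."""
        rng = np.random.default_rng(5)
        n_draws = 20_000
        checked = 0
        for _ in range(20):
            post0 = _random_niw(rng, 2)
            post1 = _random_niw(rng, 2)
            a1 = float(rng.uniform(0.25, 0.75))
            clf = sb.build_obc(post0, post1, alpha1=a1)
            x = rng.normal(size=2) + 0.5 * (post0.m + post1.m)
            sides = []
            for post, w in ((post0, 1 - a1), (post1, a1)):
                dens = w * _niw_predictive_draws(rng, post, x, n_draws)
                sides.append((dens.mean(), dens.std(ddof=1) / np.sqrt(n_draws)))
            diff = sides[0][0] - sides[1][0]
            se = np.hypot(sides[0][1], sides[1][1])
            if abs(diff) > 3 * se:
                checked += 1
                assert clf.classify(x) == (0 if diff > 0 else 1)
        assert checked >= 10  # most instances should be conclusive


def _niw_predictive_draws(rng, post, x, n_draws):
    """Gaussian density f(x | mu, Sigma) under draws from the NIW posterior."""
    d = post.dim
    sigmas = invwishart.rvs(df=post.kappa, scale=post.Psi, size=n_draws,
                            random_state=rng)
    sigmas = sigmas.reshape(n_draws, d, d)
    chols = np.linalg.cholesky(sigmas)
    z = rng.standard_normal((n_draws, d))
    mus = post.m + np.einsum("kij,kj->ki", chols, z) / np.sqrt(post.nu)
    dev = x - mus
    sol = np.linalg.solve(sigmas, dev[..., None])[..., 0]
    quad_form = np.einsum("ki,ki->k", dev, sol)
    _, logdets = np.linalg.slogdet(sigmas)
    return np.exp(-0.5 * (d * np.log(2 * np.pi) + logdets + quad_form))


class TestQDABuilders:
    def test_identical_specs_give_half_error(self, ou, ou_grid_small):
        clf = sb.build_qda_from_sde(ou, ou, ou_grid_small, alpha1=0.5)
        te0 = sb.simulate_paths(ou, ou_grid_small, n=200, seed=6, label=0)
        te1 = sb.simulate_paths(ou, ou_grid_small, n=200, seed=7, label=1)
        # fully symmetric discriminant is identically zero; every path gets
        # the same label, so the mixing-weighted error is exactly one half
        assert np.all(clf.discriminant(te0) == 0.0)
        assert sb.true_error(clf, te0, te1, alpha1=0.5) == 0.5

    def test_simulated_moments_approach_analytic_classifier(self):
        spec0 = sb.ou_spec(0.1, 80.0, 1.0, 1.0)
        spec1 = sb.ou_spec(0.1, 85.0, 1.0, 1.0)
        grid = sb.ObservationGrid(np.arange(1.0, 6.0), 1)
        analytic = sb.build_qda_from_sde(spec0, spec1, grid, alpha1=0.5)
        # fine substeps: the comparison should measure Monte-Carlo moment
        # error, not Euler-Maruyama discretization bias
        sim = sb.build_qda_from_sde(spec0, spec1, grid, alpha1=0.5,
                                    moment_source="simulated", l=50_000,
                                    seed=31, substeps=100)
        te0 = sb.simulate_paths(spec0, grid, 500, seed=33)
        te1 = sb.simulate_paths(spec1, grid, 500, seed=34)
        X = np.vstack([te0.stacked(), te1.stacked()])
        agreement = np.mean(analytic.classify(X) == sim.classify(X))
        assert agreement >= 0.99

    def test_simulated_moments_require_l_above_dimension(self, ou, ou_grid_small):
        with pytest.raises(NumericalError):
            sb.build_qda_from_sde(ou, ou, ou_grid_small, alpha1=0.5,
                                  moment_source="simulated", l=3, seed=0)

    def test_data_qda_needs_more_paths_than_dimension(self, ou, ou_grid_small):
        tr0 = sb.simulate_paths(ou, ou_grid_small, n=3, seed=0, label=0)
        tr1 = sb.simulate_paths(ou, ou_grid_small, n=3, seed=1, label=1)
        with pytest.raises(NumericalError, match="Np"):
            sb.build_qda_from_data(tr0, tr1, alpha1=0.5)

    def test_data_qda_converges_to_plugin_decisions(self):
        spec0 = sb.ou_spec(0.1, 80.0, 1.0, 1.0)
        spec1 = sb.ou_spec(0.1, 85.0, 1.0, 1.0)
        grid = sb.ObservationGrid(np.arange(1.0, 6.0), 1)
        plugin = sb.build_qda_from_sde(spec0, spec1, grid, alpha1=0.5)
        te0 = sb.simulate_paths(spec0, grid, 500, seed=43)
        te1 = sb.simulate_paths(spec1, grid, 500, seed=44)
        X = np.vstack([te0.stacked(), te1.stacked()])
        agreements = []
        for n in (500, 10_000):
            tr0 = sb.simulate_paths(spec0, grid, n, substeps=100, seed=41, label=0)
            tr1 = sb.simulate_paths(spec1, grid, n, substeps=100, seed=42, label=1)
            data_qda = sb.build_qda_from_data(tr0, tr1, alpha1=0.5)
            agreements.append(np.mean(plugin.classify(X) == data_qda.classify(X)))
        assert agreements[1] > agreements[0]
        assert agreements[1] >= 0.98

    def test_duplicated_training_path_is_allowed(self, ou, ou_grid_small):
        tr0 = sb.simulate_paths(ou, ou_grid_small, n=6, seed=0, label=0)
        dup = sb.PathSet(grid=tr0.grid,
                         paths=np.concatenate([tr0.paths, tr0.paths[:1]]), label=0)
        tr1 = sb.simulate_paths(ou, ou_grid_small, n=7, seed=1, label=1)
        clf = sb.build_qda_from_data(dup, tr1, alpha1=0.5)
        assert clf.dim == 3
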