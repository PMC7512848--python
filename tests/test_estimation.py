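import numpy as np
import pytest
from scipy import stats

from penphi import (
    EstimationError,
    ProbabilityVector,
    asymptotic_covariance,
    fit_mpe,
    fit_mpe_batch,
    fixture,
    misspec_summary,
    penalized_divergence,
    projection_parameter,
)
from penphi.estimation import _covariance_pieces

from conftest import brute_force_theta

# land-cover worked example: printed estimates are truncated to 4 decimals,
# so a correct minimizer lies within 1e-4 above each printed value
TABLE14_THETA = {
    ("globcover-ebl", 0.5): 0.9490,
    ("globcover-ebl", 1.0): 0.9503,
    ("globcover-ebl", 2.0): 0.9527,
    ("lccci-ebl", 0.5): 0.9721,
    ("lccci-ebl", 1.0): 0.9725,
    ("lccci-ebl", 2.0): 0.9732,
}


@pytest.mark.parametrize("fx,h", sorted(TABLE14_THETA))
def test_land_cover_estimates(fx, h, hw, pd):
    est = fit_mpe(fixture(fx), hw, pd(-2), h)
    theta = est.theta_hat[0]
    printed = TABLE14_THETA[(fx, h)]
    assert printed <= theta < printed + 1e-4
    assert np.floor(theta * 1e4) / 1e4 == pytest.approx(printed)
    assert est.converged and est.min_divergence >= 0
    assert est.cov_theta is not None and est.cov_theta[0, 0] > 0


def test_perfect_fit_recovers_exactly(hw, pd):
    for lam, h in [(-2, 0.5), (0, 1.0), (1, 2.0)]:
        est = fit_mpe([25, 25, 25, 25], hw, pd(lam), h)
        assert est.theta_hat[0] == pytest.approx(0.5, abs=1e-9)
        assert est.min_divergence == pytest.approx(0.0, abs=1e-14)


def test_fit_requires_positive_total(hw, pd):
    with pytest.raises(ValueError):
        fit_mpe([0, 0, 0, 0], hw, pd(1), 1.0)
    with pytest.raises(ValueError):
        fit_mpe([1, 2, 3, 4], hw, pd(1), -1.0)


def test_optimizer_matches_grid_search_oracle(rng, pd):
    # 50 random count vectors across the three built-in models; the
    # exhaustive 1e-6-step scan is the independent oracle
    from penphi import get_model

    cases = []
    for i in range(50):
        name = ("example1", "example2", "example3-hw")[i % 3]
        model = get_model(name)
        lo, hi = model.clamped_bounds()
        t = rng.uniform(lo[0] + 0.15 * (hi[0] - lo[0]),
                        hi[0] - 0.15 * (hi[0] - lo[0]))
        X = rng.multinomial(rng.integers(30, 300), model.p([t]))
        lam = (-2, 0, 1)[i % 3]
        h = (0.5, 1.0, 2.0)[(i // 3) % 3]
        cases.append((model, X, lam, h))
    for model, X, lam, h in cases:
        q = X / X.sum()
        with np.errstate(all="ignore"):
            oracle = brute_force_theta(q, model, pd(lam), h)
        est = fit_mpe(X, model, pd(lam), h, compute_cov=False)
        assert est.theta_hat[0] == pytest.approx(oracle, abs=1.1e-5)


def test_h_has_no_effect_without_empty_cells(hw, pd):
    thetas = [
        fit_mpe([40, 30, 20, 10], hw, pd(-2), h, compute_cov=False).theta_hat[0]
        for h in (0.5, 1.0, 2.0)
    ]
    assert thetas[0] == thetas[1] == thetas[2]


def test_batch_fit_agrees_with_scalar_path(rng, hw, pd):
    X = rng.multinomial(120, hw.p([0.7]), size=40)
    batch = fit_mpe_batch(X, hw, pd(-2), 0.5)
    scalar = np.array([
        fit_mpe(x, hw, pd(-2), 0.5, compute_cov=False).theta_hat[0]
        for x in X
    ])
    assert np.allclose(batch, scalar, atol=1e-7)


def test_estimator_consistency_root_n_rate(hw, pd):
    # median |theta_hat - theta*| should halve as n quadruples
    theta_star, reps = 0.8, 600
    rng = np.random.default_rng(77)
    medians = []
    for n in (250, 1000, 4000):
        X = rng.multinomial(n, hw.p([theta_star]), size=reps)
        th = fit_mpe_batch(X, hw, pd(-2), 0.5)
        medians.append(np.median(np.abs(th - theta_star)))
    for a, b in zip(medians, medians[1:]):
        assert 0.38 < b / a < 0.65


def test_estimator_asymptotic_normality(hw, pd):
    # standardized estimates at large n pass a skewness/kurtosis sanity check
    theta_star, n, reps = 0.8, 10_000, 5_000
    rng = np.random.default_rng(3)
    X = rng.multinomial(n, hw.p([theta_star]), size=reps)
    th = fit_mpe_batch(X, hw, pd(-2), 0.5)
    z = np.sqrt(n) * (th - theta_star)
    z = (z - z.mean()) / z.std()
    assert abs(stats.skew(z)) < 0.15
    assert abs(stats.kurtosis(z)) < 0.3


class TestProjectionParameter:
    def test_recovers_member_of_family(self, hw, pd):
        pi = hw.p([0.2])
        t0 = projection_parameter(pi, hw, pd(1), 1.0)
        assert t0[0] == pytest.approx(0.2, abs=1e-8)

    def test_matches_grid_oracle_off_family(self, ex1, pd):
        pi = np.array([0.3, 0.3, 0.4])
        t0 = projection_parameter(pi, ex1, pd(1), 1.0)
        oracle = brute_force_theta(pi, ex1, pd(1), 1.0)
        assert t0[0] == pytest.approx(oracle, abs=1e-5)

    def test_penalty_irrelevant_without_zeros(self, ex1, pd):
        pi = np.array([0.3, 0.3, 0.4])
        a = projection_parameter(pi, ex1, pd(1), 0.5)
        b = projection_parameter(pi, ex1, pd(1), 2.0)
        assert a[0] == b[0]

    def test_gradient_condition_at_interior_projection(self, ex1, pd):
        pi = np.array([0.3, 0.3, 0.4])
        phi = pd(1)
        t0 = projection_parameter(pi, ex1, phi, 1.0)
        J = ex1.jacobian(t0)
        x = pi / ex1.p(t0)
        v = phi.value(x) - x * phi.d1(x)  # m = k: no penalty term
        assert np.abs(J @ v).max() <= 1e-6


class TestAsymptoticCovariance:
    def test_fisher_information_limit(self, hw, pd):
        # MLE-generating divergence at a model point: inverse Fisher
        # information; for the Hardy-Weinberg law var = theta(1-theta)/2
        pi = ProbabilityVector.from_array(hw.p([0.5]))
        cov = asymptotic_covariance(pi, hw, [0.5], pd(0), 1.0)
        assert cov[0, 0] == pytest.approx(0.125, abs=1e-6)

    def test_fisher_limit_other_theta(self, hw, pd):
        t = 0.3
        pi = ProbabilityVector.from_array(hw.p([t]))
        cov = asymptotic_covariance(pi, hw, [t], pd(0), 1.0)
        assert cov[0, 0] == pytest.approx(t * (1 - t) / 2, rel=1e-8)

    def test_symmetric_psd(self, ex1, pd, rng):
        for _ in range(5):
            pi = rng.dirichlet(np.ones(3))
            t0 = projection_parameter(pi, ex1, pd(1), 1.0)
            cov = asymptotic_covariance(pi, ex1, t0, pd(1), 1.0)
            assert np.allclose(cov, cov.T)
            assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)

    def test_matches_empirical_variance(self, ex1, pd):
        # Monte-Carlo oracle at moderate scale; the full-size check runs in
        # the acceptance suite
        pi = np.array([0.3, 0.3, 0.4])
        t0 = projection_parameter(pi, ex1, pd(1), 1.0)
        cov = asymptotic_covariance(pi, ex1, t0, pd(1), 1.0)
        rng = np.random.default_rng(11)
        n, reps = 10_000, 6_000
        X = rng.multinomial(n, pi, size=reps)
        th = fit_mpe_batch(X, ex1, pd(1), 1.0)
        emp = n * np.var(th)
        assert emp == pytest.approx(cov[0, 0], rel=0.07)


class TestMisspecSummary:
    def test_null_case_collapses(self, hw, pd):
        pi = hw.p([0.35])
        s = misspec_summary(pi, hw, pd(1), 1.0, pd(1), 1.0)
        assert s.theta0[0] == pytest.approx(0.35, abs=1e-8)
        assert s.limit_divergence == pytest.approx(0.0, abs=1e-12)
        assert s.rho2 == pytest.approx(0.0, abs=1e-10)

    def test_rho2_h_invariant_when_fully_supported(self, ex1, pd):
        pi = np.array([0.25, 0.35, 0.4])
        vals = [
            misspec_summary(pi, ex1, pd(1), h1, pd(-2), h2).rho2
            for h1, h2 in [(0.5, 0.5), (1.0, 2.0), (2.0, 0.5)]
        ]
        assert vals[0] == pytest.approx(vals[1], rel=1e-10)
        assert vals[0] == pytest.approx(vals[2], rel=1e-10)

    def test_rho2_matches_numeric_delta_method(self, ex1, pd):
        # independent route: numerically differentiate the composite map
        # u -> D_{phi1,h1}(u, P(g(u))) and assemble the sandwich by hand
        pi = np.array([0.25, 0.35, 0.4])
        phi1, h1, phi2, h2 = pd(1), 1.0, pd(-2), 0.5
        s = misspec_summary(pi, ex1, phi1, h1, phi2, h2)

        def F(u):
            t = projection_parameter(u, ex1, phi2, h2)
            return penalized_divergence(u, ex1.p(t), phi1, h1)

        delta = 1e-6
        grad = np.empty(3)
        for j in range(3):
            up, dn = pi.copy(), pi.copy()
            up[j] += delta
            dn[j] -= delta
            grad[j] = (F(up) - F(dn)) / (2 * delta)
        Sigma = np.diag(pi) - np.outer(pi, pi)
        rho2_numeric = grad @ Sigma @ grad
        assert s.rho2 == pytest.approx(rho2_numeric, rel=1e-4)

    def test_pieces_shapes_and_d2_positive(self, ex1, pd):
        pi = np.array([0.25, 0.35, 0.4])
        s = misspec_summary(pi, ex1, pd(1), 1.0, pd(-2), 0.5)
        m = 3
        assert s.G.shape == (1, m) and s.D1.shape == (1, m)
        assert s.D2.shape == (1, 1) and s.D2[0, 0] > 0
        assert s.v.shape == (m,) and s.varpi.shape == (m,)
        assert s.positive_cells.tolist() == [0, 1, 2]
        assert s.rho2 >= 0

    def test_empty_cell_summary_uses_positive_support(self, hw, pd):
        pi = np.array([0.5, 0.3, 0.2, 0.0])
        s = misspec_summary(pi, hw, pd(-2), 0.5, pd(-2), 0.5)
        assert s.positive_cells.tolist() == [0, 1, 2]
        assert s.G.shape == (1, 3)
        assert np.isfinite(s.rho2) and s.rho2 > 0


def test_covariance_pieces_gradient_identity(ex1, pd):
    # Eq-(4)-style identity: at theta0 the weighted jacobian annihilates v
    pi = np.array([0.3, 0.3, 0.4])
    phi = pd(1)
    t0 = projection_parameter(pi, ex1, phi, 1.0)
    pos, x, v, w, varpi, D1, D2, G, Sigma = _covariance_pieces(
        pi, ex1, t0, phi, 1.0
    )
    assert np.abs(D1 @ v).max() <= 1e-6
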