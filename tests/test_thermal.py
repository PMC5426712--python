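"""Analytic thermal-ensemble theory against closed forms and MC oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from sascov import (
    ApproximationBreakdownError,
    ProfileCovariance,
    Structure,
    assign_tau,
    bivariate_normal_approx,
    correlation_matrix,
    covariance_matrix,
    debye_intensity,
    distance_matrix,
    geometric_nu,
    mean_intensity,
    mean_intensity_uniform,
    mixture_mean_intensity,
    noncentral_chi_pdf,
    point_model,
    sinc,
    sinc_expectation,
)
from sascov.thermal import noncentral_chi_cdf
from sascov.synthetic import ToySpec, make_toy_structure, mc_mean_cov, oracle_allowance


class TestNoncentralChi:
    @pytest.mark.parametrize("d0,tk,tl", [(5.0, 0.5, 0.5), (2.0, 0.1, 0.3), (30.0, 2.0, 1.0)])
    def test_integrates_to_one(self, d0, tk, tl):
        total, _ = quad(lambda d: noncentral_chi_pdf(d, d0, tk, tl), 0, d0 + 40 * (tk + tl))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_zero_distance_has_zero_density(self):
        assert noncentral_chi_pdf(0.0, 5.0, 0.5, 0.5) == 0.0

    def test_rigid_pair_rejected(self):
        with pytest.raises(ValueError):
            noncentral_chi_pdf(1.0, 5.0, 0.0, 0.0)

    def test_cdf_differentiates_to_pdf(self):
        d = np.linspace(0.5, 10.0, 50)
        h = 1e-5
        num = (noncentral_chi_cdf(d + h, 5.0, 0.6, 0.8) - noncentral_chi_cdf(d - h, 5.0, 0.6, 0.8)) / (2 * h)
        np.testing.assert_allclose(num, noncentral_chi_pdf(d, 5.0, 0.6, 0.8), rtol=1e-6, atol=1e-10)

    def test_matches_sampled_distances(self):
        """KS test: |N(p1, tk^2 I) - N(p2, tl^2 I)| follows the density."""
        rng = np.random.default_rng(2718)
        d0, tk, tl = 8.0, 0.7, 0.4
        n = 100_000
        delta = rng.standard_normal((n, 3)) * np.sqrt(tk**2 + tl**2)
        delta[:, 0] += d0
        sample = np.linalg.norm(delta, axis=1)
        stat = kstest(sample, lambda d: noncentral_chi_cdf(d, d0, tk, tl))
        assert stat.pvalue > 0.01


class TestSincExpectation:
    def test_q_zero_is_one(self):
        assert sinc_expectation(0.0, 10.0, 0.5, 0.5) == 1.0

    def test_rigid_limit_is_sinc(self):
        q = np.linspace(0, 0.5, 11)
        np.testing.assert_allclose(sinc_expectation(q, 7.0, 0.0, 0.0), sinc(q * 7.0), rtol=1e-15)

    @pytest.mark.parametrize("q,d0,tk,tl,seed", [
        (0.3, 10.0, 0.5, 0.5, 1),
        (0.45, 3.0, 1.5, 0.2, 2),
        (0.1, 40.0, 2.0, 2.0, 3),
    ])
    def test_exact_against_monte_carlo(self, q, d0, tk, tl, seed):
        """The closed form is exact: deviations are pure sampling error."""
        rng = np.random.default_rng(seed)
        n = 1_000_000
        delta = rng.standard_normal((n, 3)) * np.sqrt(tk**2 + tl**2)
        delta[:, 0] += d0
        x = np.sinc(q * np.linalg.norm(delta, axis=1) / np.pi)
        se = x.std(ddof=1) / np.sqrt(n)
        assert abs(sinc_expectation(q, d0, tk, tl) - x.mean()) < 3 * se


class TestMeanIntensity:
    def test_zero_tau_equals_rigid(self, cloud10, point_ff):
        s = assign_tau(cloud10, "uniform", 0.0)
        q = np.linspace(0, 0.5, 21)
        np.testing.assert_allclose(
            mean_intensity(s, q, point_ff).intensity,
            debye_intensity(s, q, point_ff).intensity,
            rtol=1e-13,
        )

    def test_uniform_specialization_identity(self, cloud10, point_ff):
        q = np.linspace(0, 0.5, 31)
        general = mean_intensity(cloud10, q, point_ff).intensity
        special = mean_intensity_uniform(cloud10, 0.5, q, point_ff).intensity
        np.testing.assert_allclose(general, special, rtol=1e-12)

    def test_requires_tau(self, two_point_atoms, point_ff):
        with pytest.raises(ValueError, match="assign_tau"):
            mean_intensity(two_point_atoms, ff=point_ff)

    def test_against_mc_oracle(self, point_ff):
        """5-atom toy: analytic mean within 3 SE of the sampled mean."""
        s = make_toy_structure(ToySpec(kind="random-cloud", n_atoms=5, scale=8.0, tau=0.5, seed=9, element="X"))
        q = np.linspace(0, 0.5, 26)
        mc = mc_mean_cov(s, q, point_ff, n_samples=40_000, seed=21)
        ana = mean_intensity(s, q, point_ff).intensity
        dev = np.abs(ana - mc.mean.intensity)
        pos = mc.mean_se > 0
        assert np.all(dev[~pos] == 0)  # I(0) is deterministic with f = 1
        # 4-SE family-wise gate over the 26-point grid (per-point z is
        # standard normal because the closed form is exact)
        assert np.all(dev[pos] < 4 * mc.mean_se[pos])

    def test_uniform_limits_and_convexity(self, cloud10, point_ff):
        q = np.linspace(0, 0.5, 21)
        rigid = debye_intensity(cloud10, q, point_ff).intensity
        floor = float(cloud10.n_atoms)  # sum f^2 with f = 1
        # large q*tau: mean approaches the self-term floor
        big = mean_intensity_uniform(cloud10, 300.0, q, point_ff).intensity
        np.testing.assert_allclose(big[1:], floor, rtol=1e-6)
        # convex combination stays between the two envelopes
        mid = mean_intensity_uniform(cloud10, 1.0, q, point_ff).intensity
        lo = np.minimum(rigid, floor) - 1e-9
        hi = np.maximum(rigid, floor) + 1e-9
        assert np.all(mid >= lo) and np.all(mid <= hi)


class TestMixture:
    def test_single_component_identity(self, cloud10, point_ff):
        q = np.linspace(0, 0.5, 11)
        mix = mixture_mean_intensity([(cloud10, 0.5, 1.0)], q, point_ff).intensity
        np.testing.assert_allclose(mix, mean_intensity_uniform(cloud10, 0.5, q, point_ff).intensity)

    def test_two_identical_components(self, cloud10, point_ff):
        q = np.linspace(0, 0.5, 11)
        mix = mixture_mean_intensity([(cloud10, 0.5, 0.5), (cloud10, 0.5, 0.5)], q, point_ff).intensity
        np.testing.assert_allclose(mix, mean_intensity_uniform(cloud10, 0.5, q, point_ff).intensity, rtol=1e-14)

    def test_unnormalized_weights_error(self, cloud10, point_ff):
        with pytest.raises(ValueError, match="sum to 1"):
            mixture_mean_intensity([(cloud10, 0.5, 0.7), (cloud10, 3.0, 0.7)], ff=point_ff)

    def test_floppy_component_decays_faster(self, cloud10, point_ff):
        """With tau_A << tau_B the B term's coherent (non-floor) part dies
        off in q much faster, so the rigid state dominates at high angle."""
        q = np.array([0.05, 0.4])
        rigid = debye_intensity(cloud10, q, point_ff).intensity
        floor = float(cloud10.n_atoms)
        def nonfloor(tau):
            return np.exp(-q**2 * tau**2) * (rigid - floor)
        ratio_A = nonfloor(0.3)[1] / nonfloor(0.3)[0]
        ratio_B = nonfloor(3.0)[1] / nonfloor(3.0)[0]
        assert abs(ratio_B) < abs(ratio_A)


class TestGeometricNu:
    def test_collinear_opposite(self):
        s = Structure(elements=["X"] * 3, coords=[[0, 0, 0], [-2, 0, 0], [3, 0, 0]])
        assert geometric_nu(s, 0, 1, 2) == pytest.approx(-1.0)

    def test_right_angle(self):
        s = Structure(elements=["X"] * 3, coords=[[0, 0, 0], [2, 0, 0], [0, 5, 0]])
        assert geometric_nu(s, 0, 1, 2) == pytest.approx(0.0, abs=1e-15)

    def test_random_triple_matches_dot_product(self):
        rng = np.random.default_rng(31)
        coords = rng.standard_normal((3, 3)) * 4
        s = Structure(elements=["X"] * 3, coords=coords)
        u, v = coords[1] - coords[0], coords[2] - coords[0]
        expected = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        assert geometric_nu(s, 0, 1, 2) == pytest.approx(expected, rel=1e-12)

    def test_coincident_atoms_error(self):
        s = Structure(elements=["X"] * 3, coords=[[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            geometric_nu(s, 0, 1, 2)


class TestBivariateNormalApprox:
    def test_rigid_shared_atom_decorrelates(self):
        _, cov = bivariate_normal_approx(10.0, 12.0, 0.5, 0.0, 0.4, 0.3)
        assert cov[0, 1] == 0.0

    def test_perfectly_correlated_rank_one(self):
        _, cov = bivariate_normal_approx(10.0, 12.0, 1.0, 0.5, 0.0, 0.0)
        assert np.linalg.matrix_rank(cov, tol=1e-12) == 1

    def test_warns_on_large_tau(self):
        with pytest.warns(RuntimeWarning, match="tau/d0"):
            bivariate_normal_approx(1.0, 1.0, 0.0, 0.5, 0.5, 0.5)

    def test_moments_against_sampling(self):
        """tau/d0 = 0.02: empirical mean and covariance of (d_kl, d_kn)."""
        rng = np.random.default_rng(77)
        pk = np.zeros(3)
        pl = np.array([10.0, 0.0, 0.0])
        pn = np.array([3.0, 11.0, 0.0])
        d0_kl = np.linalg.norm(pl - pk)
        d0_kn = np.linalg.norm(pn - pk)
        nu = (pl - pk) @ (pn - pk) / (d0_kl * d0_kn)
        tk = tl = tn = 0.02 * min(d0_kl, d0_kn)
        n = 1_000_000
        xk = pk + rng.standard_normal((n, 3)) * tk
        xl = pl + rng.standard_normal((n, 3)) * tl
        xn = pn + rng.standard_normal((n, 3)) * tn
        dkl = np.linalg.norm(xl - xk, axis=1)
        dkn = np.linalg.norm(xn - xk, axis=1)
        mean, cov = bivariate_normal_approx(d0_kl, d0_kn, nu, tk, tl, tn)
        eps = (tk / min(d0_kl, d0_kn)) ** 2
        # means agree to O((tau/d)^2) relative (the shift term itself is
        # second order, so allow a few eps of slack plus MC error)
        assert abs(dkl.mean() - mean[0]) < 5 * eps * d0_kl + 4 * dkl.std() / np.sqrt(n)
        emp_cov = np.cov(dkl, dkn)
        scale = max(tk**2 + tl**2, abs(cov[0, 1]))
        assert np.abs(emp_cov - cov).max() < 0.05 * scale


def _toy_with_tau(ratio=0.02, seed=42):
    s = make_toy_structure(ToySpec(kind="random-cloud", n_atoms=5, scale=8.0, seed=seed, element="X"))
    D = distance_matrix(s)
    dmin = D[D > 0].min()
    return assign_tau(s, "uniform", ratio * dmin), dmin


class TestCovarianceMatrix:
    def test_two_atom_closed_form(self, point_ff):
        """Hand-linearized 2-atom system: V = 4 (t1^2+t2^2) qi qj s(qi d) s(qj d)."""
        from sascov import sigma_kernel

        s = Structure(elements=["X", "X"], coords=[[0, 0, 0], [6.0, 0, 0]], tau=[0.2, 0.3])
        q = np.linspace(0, 0.5, 11)
        cov = covariance_matrix(s, q, point_ff)
        t2 = 0.2**2 + 0.3**2
        expected = 4 * t2 * np.outer(q * sigma_kernel(q * 6.0), q * sigma_kernel(q * 6.0))
        np.testing.assert_allclose(cov.cov, expected, rtol=1e-12, atol=1e-18)

    def test_two_atoms_have_no_cross_term(self, point_ff):
        s = Structure(elements=["X", "X"], coords=[[0, 0, 0], [6.0, 0, 0]], tau=[0.2, 0.3])
        cov = covariance_matrix(s, np.linspace(0, 0.5, 11), point_ff)
        np.testing.assert_array_equal(cov.cross, 0.0)

    def test_q_zero_row_is_exactly_zero(self, point_ff):
        s, _ = _toy_with_tau(0.05)
        cov = covariance_matrix(s, np.linspace(0, 0.5, 21), point_ff)
        assert np.all(cov.cov[0, :] == 0.0) and np.all(cov.cov[:, 0] == 0.0)

    def test_symmetry_and_zero_tau(self, point_ff):
        s, _ = _toy_with_tau(0.05)
        q = np.linspace(0, 0.5, 16)
        cov = covariance_matrix(s, q, point_ff)
        np.testing.assert_allclose(cov.cov, cov.cov.T, rtol=1e-12)
        rigid = assign_tau(s, "uniform", 0.0)
        np.testing.assert_array_equal(covariance_matrix(rigid, q, point_ff).cov, 0.0)

    def test_tau_squared_scaling(self, point_ff):
        """Both kernels are linear in tau^2: V(2 tau) = 4 V(tau) to O(tau^2)."""
        s1, _ = _toy_with_tau(0.01)
        s2, _ = _toy_with_tau(0.02)
        q = np.linspace(0, 0.5, 16)
        v1 = covariance_matrix(s1, q, point_ff).cov
        v2 = covariance_matrix(s2, q, point_ff).cov
        np.testing.assert_allclose(v2, 4.0 * v1, rtol=1e-10, atol=1e-30)

    def test_against_mc_oracle(self, point_ff):
        """Quadruple-sum prefactors and kernels versus brute-force MC."""
        s, dmin = _toy_with_tau(0.04)
        q = np.linspace(0, 0.5, 13)
        ana = covariance_matrix(s, q, point_ff)
        mc = mc_mean_cov(s, q, point_ff, n_samples=60_000, seed=13)
        allow = oracle_allowance(q, float(s.tau[0]), dmin, ana.cov)
        dev = np.abs(ana.cov - mc.cov.cov)
        assert np.all(dev <= 3 * mc.cov_se + allow + 1e-30)

    def test_max_atoms_guard(self, point_ff):
        s = make_toy_structure(ToySpec(kind="globule", n_atoms=30, scale=10.0, tau=0.1, seed=1, element="X"))
        with pytest.raises(ValueError, match="max_atoms"):
            covariance_matrix(s, np.linspace(0, 0.5, 5), point_ff, max_atoms=10)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_range(self, point_ff):
        s, _ = _toy_with_tau(0.05)
        cov = covariance_matrix(s, np.linspace(0, 0.5, 21), point_ff)
        corr = correlation_matrix(cov)
        finite = np.isfinite(corr.rho)
        assert np.all(np.abs(corr.rho[finite]) <= 1.0)
        idx = np.arange(1, 21)
        np.testing.assert_array_equal(corr.rho[idx, idx], 1.0)

    def test_q_zero_marked_undefined(self, point_ff):
        s, _ = _toy_with_tau(0.05)
        cov = covariance_matrix(s, np.linspace(0, 0.5, 11), point_ff)
        corr = correlation_matrix(cov)
        assert np.all(np.isnan(corr.rho[0, :])) and np.all(np.isnan(corr.rho[:, 0]))

    def test_rank_one_covariance_gives_unit_correlation(self):
        q = np.linspace(0.01, 0.5, 8)
        v = np.sin(q * 10) + 1.5
        corr = correlation_matrix(ProfileCovariance(q, np.outer(v, v)))
        np.testing.assert_allclose(np.abs(corr.rho), 1.0, rtol=1e-12)

    def test_negative_diagonal_raises_breakdown(self):
        q = np.array([0.1, 0.2])
        bad = np.array([[1.0, 0.0], [0.0, -0.5]])
        with pytest.raises(ApproximationBreakdownError, match="second-order"):
            correlation_matrix(ProfileCovariance(q, bad))
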