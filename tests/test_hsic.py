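"""HSIC, distance correlation and kernel plumbing."""

import numpy as np
import pytest

import wntgsa as w
from wntgsa.errors import DegenerateDataError, InputError
from wntgsa.hsic import KernelSpec, gram_matrix


def hsic_expansion(x, u, spec):
    """Brute-force three-term expansion of the biased HSIC estimator."""
    Kx, Ku = gram_matrix(x, spec), gram_matrix(u, spec)
    n = len(x)
    t1 = (Kx * Ku).sum() / n**2
    t2 = Kx.sum() / n**2 * Ku.sum() / n**2
    t3 = (2.0 / n) * np.sum(Kx.mean(axis=1) * Ku.mean(axis=1))
    return t1 + t2 - t3


class TestGram:
    def test_rbf_unit_diagonal_and_symmetry(self):
        x = np.random.default_rng(0).normal(size=12)
        K = gram_matrix(x, KernelSpec("rbf"))
        assert np.allclose(np.diag(K), 1.0)
        assert np.array_equal(K, K.T)

    def test_laplace_wide_bandwidth_limit(self):
        x = np.random.default_rng(1).normal(size=8)
        K = gram_matrix(x, KernelSpec("laplace", bandwidth=1e9))
        assert np.allclose(K, 1.0, atol=1e-6)

    def test_linear_kernel_is_outer_product(self):
        x = np.array([1.0, 2.0, -1.0])
        K = gram_matrix(x, KernelSpec("linear"))
        assert np.allclose(K, np.outer(x, x))

    def test_positive_semidefinite(self):
        x = np.random.default_rng(2).normal(size=20)
        for fam in ("linear", "rbf", "laplace"):
            K = gram_matrix(x, KernelSpec(fam))
            assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_invalid_specs(self):
        with pytest.raises(InputError):
            KernelSpec("poly")
        with pytest.raises(InputError):
            KernelSpec("rbf", bandwidth=-1.0)


class TestCenteringMatrix:
    def test_two_by_two(self):
        assert np.allclose(w.centering_matrix(2), [[0.5, -0.5], [-0.5, 0.5]])

    def test_annihilates_constants_and_idempotent(self):
        H = w.centering_matrix(7)
        assert np.allclose(H @ np.ones(7), 0.0, atol=1e-12)
        assert np.allclose(H @ H, H, atol=1e-12)
        assert np.allclose(H.sum(axis=1), 0.0, atol=1e-12)

    def test_invalid_size(self):
        with pytest.raises(InputError):
            w.centering_matrix(0)


class TestMedianHeuristic:
    def test_single_pair(self):
        assert w.median_heuristic_bandwidth([0.0, 2.0]) == pytest.approx(2.0)

    def test_enumerated_triple(self):
        # pairwise distances {2-0, 3-0, 3-1} wait: (0,1,3) -> {1, 3, 2}, median 2
        assert w.median_heuristic_bandwidth([0.0, 1.0, 3.0]) == pytest.approx(2.0)

    def test_scale_homogeneity(self):
        x = np.random.default_rng(3).normal(size=25)
        assert w.median_heuristic_bandwidth(5.0 * x) == pytest.approx(
            5.0 * w.median_heuristic_bandwidth(x)
        )

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateDataError):
            w.median_heuristic_bandwidth(np.ones(10))


class TestHsic:
    def test_trace_matches_expansion_oracle(self):
        """Trace estimator equals the three-term expansion to 1e-10."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            x, u = rng.normal(size=n), rng.normal(size=n)
            for fam in ("linear", "rbf", "laplace"):
                spec = KernelSpec(fam)
                assert w.hsic(x, u, spec, spec) == pytest.approx(
                    hsic_expansion(x, u, spec), abs=1e-10
                )

    def test_constant_input_gives_zero(self):
        u = np.random.default_rng(5).normal(size=10)
        spec = KernelSpec("rbf", bandwidth=1.0)
        assert w.hsic(np.ones(10), u, spec, spec) == pytest.approx(0.0, abs=1e-12)

    def test_linear_kernel_equals_squared_covariance(self):
        rng = np.random.default_rng(6)
        x, u = rng.normal(size=15), rng.normal(size=15)
        spec = KernelSpec("linear")
        n = 15
        cov_biased = ((x - x.mean()) * (u - u.mean())).sum() / n
        assert w.hsic(x, u, spec, spec) == pytest.approx(cov_biased**2, abs=1e-10)

    def test_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, u = rng.normal(size=12), rng.normal(size=12)
            assert w.hsic(x, u, KernelSpec("rbf"), KernelSpec("rbf")) >= -1e-12


class TestDistanceCorrelation:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(8).normal(size=40)
        assert w.hsic_index(x, x, KernelSpec("rbf")).value == pytest.approx(1.0, abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            x, u = rng.normal(size=20), rng.normal(size=20)
            R = w.hsic_index(x, u, KernelSpec("rbf")).value
            assert -1e-8 <= R <= 1 + 1e-8

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        x, u = rng.normal(size=30), rng.normal(size=30)
        spec = KernelSpec("laplace")
        assert w.hsic_index(x, u, spec).value == pytest.approx(
            w.hsic_index(u, x, spec).value, abs=1e-12
        )

    def test_translation_invariance_of_stationary_kernels(self):
        rng = np.random.default_rng(11)
        x, u = rng.normal(size=30), rng.normal(size=30)
        for fam in ("rbf", "laplace"):
            spec = KernelSpec(fam, bandwidth=1.0)
            r0 = w.hsic_index(x, u, spec).value
            r1 = w.hsic_index(x + 100.0, u - 5.0, spec).value
            assert r1 == pytest.approx(r0, abs=1e-10)

    def test_rbf_sees_quadratic_dependence_linear_does_not(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(-1, 1, 300)
        u = x**2
        r_rbf = w.hsic_index(x, u, KernelSpec("rbf")).value
        r_lin = w.hsic_index(x, u, KernelSpec("linear")).value
        assert r_rbf > 5 * r_lin

    def test_constant_variable_degenerate(self):
        with pytest.raises(DegenerateDataError):
            w.hsic_index(np.ones(10), np.arange(10.0), KernelSpec("rbf", bandwidth=1.0))

    def test_matrix_fast_path_matches_per_column(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 3))
        u = X[:, 0] + rng.normal(size=40)
        spec = KernelSpec("rbf")
        fast = w.hsic_indices_matrix(X, u, spec)
        for j, est in enumerate(fast):
            assert est.value == pytest.approx(w.hsic_index(X[:, j], u, spec).value, abs=1e-12)


class TestPermutationDiagnostic:
    def test_detects_nonlinear_dependence(self):
        """rbf R separates u = sin(3x) + noise from the null at level 0.05."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-2, 2, 200)
            u = np.sin(3 * x) + 0.3 * rng.normal(size=200)
            res = w.hsic_permutation_test(x, u, KernelSpec("rbf"), n_permutations=100,
                                          rng_seed=seed)
            hits += res["p_value"] <= 0.05
        assert hits >= 38

    def test_null_calibration(self):
        low = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            x, u = rng.normal(size=200), rng.normal(size=200)
            res = w.hsic_permutation_test(x, u, KernelSpec("rbf"), n_permutations=100,
                                          rng_seed=seed)
            low += res["R"] < res["null_q95"]
        assert low >= 33  # ~95% expected below the null 95th percentile
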