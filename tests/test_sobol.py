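"""Pick-freeze Sobol estimators against analytic and structural oracles."""

import numpy as np
import pytest
from scipy import stats

import wntgsa as w
from wntgsa.errors import DegenerateDataError, InputError


def first_and_total(estimates):
    firsts = np.array([e.value for e in estimates if e.order == "first"])
    totals = np.array([e.value for e in estimates if e.order == "total"])
    return firsts, totals


class TestDesign:
    def test_swap_construction(self):
        des = w.build_design(4, 2, 0)
        ab1 = des.ab(0)
        assert np.array_equal(ab1[:, 1], des.A[:, 1])
        assert np.array_equal(ab1[:, 0], des.B[:, 0])

    def test_seed_reproducibility(self):
        d1, d2 = w.build_design(16, 3, 9), w.build_design(16, 3, 9)
        assert np.array_equal(d1.A, d2.A) and np.array_equal(d1.B, d2.B)

    def test_columns_uniform_by_ks(self):
        """KS statistic below the 1% critical value in >= 95% of columns."""
        crit = stats.ksone.ppf(0.995, 10**4)  # two-sided 1% critical value
        ok = total = 0
        for seed in range(5):
            des = w.build_design(10**4, 4, seed)
            for M in (des.A, des.B):
                for j in range(4):
                    total += 1
                    ok += stats.kstest(M[:, j], "uniform").statistic < crit
        assert ok / total >= 0.95

    def test_invalid_sizes(self):
        with pytest.raises(InputError):
            w.build_design(1, 2, 0)
        with pytest.raises(InputError):
            w.build_design(8, 0, 0)


class TestCenterOutput:
    def test_basic_and_idempotent(self):
        out = w.center_output([1.0, 2.0, 3.0])
        assert np.allclose(out, [-1, 0, 1])
        assert np.allclose(w.center_output(out), out)

    def test_variance_preserved(self):
        v = np.random.default_rng(0).normal(3.0, 2.0, 100)
        assert np.var(w.center_output(v)) == pytest.approx(np.var(v), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            w.center_output([])


class TestEstimateSobol:
    @pytest.mark.parametrize("method", w.SOBOL_METHODS)
    def test_additive_symmetric_model(self, method):
        des = w.build_design(2**13, 2, 1)
        ests = w.estimate_sobol(lambda X: X[:, 0] + X[:, 1], des, method)
        S, T = first_and_total(ests)
        assert S == pytest.approx([0.5, 0.5], abs=0.02)
        assert T == pytest.approx([0.5, 0.5], abs=0.02)

    @pytest.mark.parametrize("method", w.SOBOL_METHODS)
    def test_single_active_factor(self, method):
        des = w.build_design(2**13, 2, 2)
        ests = w.estimate_sobol(lambda X: X[:, 0], des, method)
        S, T = first_and_total(ests)
        assert S == pytest.approx([1.0, 0.0], abs=0.02)
        assert T == pytest.approx([1.0, 0.0], abs=0.02)

    def test_jansen_matches_analytic_gfunction(self):
        model = w.GFunctionModel(np.array([0.0, 1.0]))
        S_true, _ = w.g_function_analytic_indices(model)
        des = w.build_design(2**14, 2, 3)
        S, _ = first_and_total(w.estimate_sobol(model, des, "jansen"))
        assert S == pytest.approx(S_true, abs=0.02)

    def test_estimator_agreement_on_benchmark(self):
        model = w.GFunctionModel(np.array([0.0, 1.0, 4.5]))
        des = w.build_design(2**14, 3, 4)
        all_S = [first_and_total(w.estimate_sobol(model, des, m))[0] for m in w.SOBOL_METHODS]
        for S in all_S[1:]:
            assert S == pytest.approx(all_S[0], abs=0.03)

    @pytest.mark.parametrize("method", w.SOBOL_METHODS)
    def test_independent_output_near_zero(self, method):
        """Output ignoring the inputs gives first-order indices within
        +-0.05 of 0.  (Total indices are excluded: with exogenous noise the
        pick-freeze evaluations f(A) and f(AB_i) draw fresh noise, so the
        estimator cannot credit the shared columns and reads ~1.)"""

        def noise_model(X):
            return 1.0 + np.random.default_rng(abs(hash(X.tobytes())) % 2**31).normal(
                size=X.shape[0]
            )

        des = w.build_design(2**13, 2, 6)
        S, _ = first_and_total(w.estimate_sobol(noise_model, des, method))
        assert np.all(np.abs(S) < 0.05)

    def test_linear_transformation_invariance(self):
        model = w.GFunctionModel(np.array([0.0, 2.0]))
        des = w.build_design(2**13, 2, 7)
        S1, T1 = first_and_total(w.estimate_sobol(model, des, "jansen"))
        S2, T2 = first_and_total(
            w.estimate_sobol(lambda X: 7.5 * model(X) - 3.0, des, "jansen")
        )
        assert S2 == pytest.approx(S1, abs=1e-10)
        assert T2 == pytest.approx(T1, abs=1e-10)

    def test_negative_estimates_flagged_not_clipped(self):
        def noise_model(X):
            return np.random.default_rng(abs(hash(X.tobytes())) % 2**31).normal(size=X.shape[0])

        des = w.build_design(256, 3, 8)
        ests = w.estimate_sobol(noise_model, des, "sobol1993")
        negatives = [e for e in ests if e.value < 0]
        assert negatives, "small-n noise should produce at least one negative estimate"
        assert all(e.out_of_range for e in negatives)

    def test_constant_output_degenerate(self):
        des = w.build_design(64, 2, 9)
        with pytest.raises(DegenerateDataError):
            w.estimate_sobol(lambda X: np.ones(X.shape[0]), des, "jansen")

    def test_unknown_method_rejected(self):
        des = w.build_design(8, 2, 0)
        with pytest.raises(InputError):
            w.estimate_sobol(lambda X: X[:, 0], des, "sobolX")


class TestGroupedIndices:
    def test_full_group_normalises_to_one(self):
        model = w.GFunctionModel(np.array([0.0, 1.0, 3.0]))
        des = w.build_design(2**13, 3, 10)
        est = w.estimate_sobol_order(model, des, [0, 1, 2])
        assert est.value == pytest.approx(1.0, abs=0.03)

    def test_additive_pair_group(self):
        des = w.build_design(2**13, 2, 11)
        est = w.estimate_sobol_order(lambda X: X[:, 0] + X[:, 1], des, [0, 1])
        assert est.value == pytest.approx(1.0, abs=0.02)

    def test_single_factor_group_matches_first_order(self):
        model = w.GFunctionModel(np.array([0.0, 1.0]))
        des = w.build_design(2**14, 2, 12)
        grouped = w.estimate_sobol_order(model, des, [0]).value
        S, _ = first_and_total(w.estimate_sobol(model, des, "sobol1993"))
        assert grouped == pytest.approx(S[0], abs=0.02)

    def test_empty_group_rejected(self):
        des = w.build_design(16, 2, 0)
        with pytest.raises(InputError):
            w.estimate_sobol_order(lambda X: X[:, 0], des, [])


class TestDataDrivenEstimation:
    def test_row_split_recovers_dominant_factor(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(size=(2**13, 2))
        model = w.GFunctionModel(np.array([0.0, 9.0]))
        S, _ = first_and_total(w.estimate_sobol_from_data(X, model, "jansen"))
        assert S[0] > S[1]

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            w.estimate_sobol_from_data(np.zeros((3, 2)), lambda X: X[:, 0], "jansen")
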