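"""Time-course fold-change and deviation experiments."""

import numpy as np
import pytest

import wntgsa as w
from wntgsa.errors import InputError
from wntgsa.timeseries import (
    IntervalLabel,
    deviation_series,
    sign_pattern,
    two_fold_filter,
)

HOURS = w.DEFAULT_HOURS


def course(gene, fc, pattern=None):
    return w.TimeCourse(gene, HOURS, np.asarray(fc, dtype=float), planted_pattern=pattern)


class TestDeviations:
    def test_examples_and_telescoping(self):
        tc = course("G", [1.0, 3.0, 2.0, 4.0, 5.0])
        dev = deviation_series(tc)
        assert np.allclose(dev, [2.0, -1.0, 2.0, 1.0])
        assert dev.sum() == pytest.approx(tc.fold_change[-1] - tc.fold_change[0])

    def test_constant_series_all_zero(self):
        assert np.allclose(deviation_series(course("G", [1.0] * 5)), 0.0)

    def test_needs_two_points(self):
        with pytest.raises(InputError):
            deviation_series(w.TimeCourse("G", (1.0,), np.array([1.0])))


class TestSignPattern:
    @pytest.mark.parametrize(
        "dev,expected",
        [((2, -1, 2, 1), "+-++"), ((0, 0), "00"), ((-1, 2, 3), "-++")],
    )
    def test_patterns(self, dev, expected):
        assert sign_pattern(np.array(dev, dtype=float)) == expected

    def test_roundtrip_on_pattern_book(self, default_timecourses, pattern_book):
        by_name = {tc.gene: tc for tc in default_timecourses}
        for gene, pattern in pattern_book.items():
            assert sign_pattern(deviation_series(by_name[gene])) == w.normalize_pattern(pattern)


class TestTwoFoldFilter:
    def test_examples(self):
        keep = course("A", [1.0, 2.5, 1.2, 1.1, 1.0])
        drop = course("B", [1.1, 1.5, 1.9, -1.2, 1.0])
        assert two_fold_filter([keep, drop]) == [keep]

    def test_planted_count(self):
        courses = w.generate_timecourse_dataset(n_genes=40, rng_seed=3, two_fold_fraction=0.25)
        assert len(two_fold_filter(courses)) == 10


class TestIntervalLabel:
    def test_display(self):
        assert IntervalLabel(3.0, 6.0).display == "<3,6>"
        assert IntervalLabel(1.0, 3.0).display == "<1,3>"

    def test_ordering_enforced(self):
        with pytest.raises(InputError):
            IntervalLabel(6.0, 3.0)


class TestFoldChangeExperiment:
    def test_shape_contract(self):
        courses = w.generate_timecourse_dataset(n_genes=12, rng_seed=4)
        res, log = w.fold_change_experiment(
            courses, ["hsic:rbf", "martinez"], w.NoiseConfig(n_samples=120, rng_seed=5),
            a_seed=6,
        )
        # 12 genes x 5 hours x (1 hsic row + 2 martinez orders)
        assert len(res) == 12 * 5 * 3
        assert sorted(res.hour.unique()) == list(HOURS)
        assert log["scaled"] is False and len(log["a"]) == 12

    def test_duplicated_course_gets_identical_indices(self):
        """Two genes with identical trajectories are exchangeable."""
        base = [0.5, 1.5, 0.8, 2.5, 3.0]
        courses = [course("A1", base), course("A2", base), course("B", [2.0, -1.0, 0.5, 1.0, -2.0])]
        res, _ = w.fold_change_experiment(
            courses, ["hsic:rbf"], w.NoiseConfig(n_samples=400, rng_seed=7),
            a_coefficients=np.array([0.3, 0.3, 0.6]),
        )
        for hour in HOURS:
            sub = res[res.hour == hour].set_index("gene")["value"]
            assert sub["A1"] == pytest.approx(sub["A2"], abs=0.1)

    def test_suppressed_gene_sits_in_bottom_quartile(self):
        """Near-zero fold change + near-zero planted dependence at one
        time point lands that gene's index in the bottom quartile."""
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            courses = [course("DULL", [0.05, 3.0, 3.0, 3.0, 3.0])]
            for j in range(7):
                fc = rng.uniform(0.5, 2.5, 5) * rng.choice([-1, 1], 5)
                courses.append(course(f"G{j}", fc))
            a = np.full(8, 0.5)
            a[0] = 50.0  # drive the planted gene's importance toward zero
            res, _ = w.fold_change_experiment(
                courses, ["hsic:rbf"], w.NoiseConfig(n_samples=150, rng_seed=seed),
                a_coefficients=a,
            )
            sub = res[res.hour == 1.0].set_index("gene")["value"]
            hits += sub["DULL"] <= sub.quantile(0.25)
        assert hits >= 27

    def test_grid_mismatch_rejected(self):
        c1 = course("A", [1, 2, 3, 4, 5])
        c2 = w.TimeCourse("B", (1.0, 3.0, 6.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InputError):
            w.fold_change_experiment([c1, c2], ["hsic:rbf"])


class TestDeviationExperiment:
    def test_interval_count_and_labels(self):
        courses = w.generate_timecourse_dataset(n_genes=6, rng_seed=8)
        res, log = w.deviation_experiment(
            courses, ["hsic:rbf"], w.NoiseConfig(n_samples=120, rng_seed=9), a_seed=10
        )
        assert sorted(res.interval.unique()) == sorted(["<1,3>", "<3,6>", "<6,12>", "<12,24>"])
        assert len(res) == 6 * 4
        assert log["intervals"] == ["<1,3>", "<3,6>", "<6,12>", "<12,24>"]

    def test_deviation_sample_variance_doubles_pointwise_variance(self):
        """Differencing independent endpoint draws doubles the variance."""
        courses = [course("A", [0.5, 1.0, 1.5, 2.0, 2.5])]
        noise = w.NoiseConfig(sd=0.005, n_samples=1000, rng_seed=11, jitter_factor=0.0)
        rng = np.random.default_rng(11)
        d = w.perturb_measurement(1.0, noise, rng) - w.perturb_measurement(0.5, noise, rng)
        assert d.var() == pytest.approx(2 * 0.005**2, rel=0.2)

    def test_needs_three_points(self):
        tc = w.TimeCourse("A", (1.0, 3.0), np.array([1.0, 2.0]))
        with pytest.raises(InputError):
            w.deviation_experiment([tc], ["hsic:rbf"])

    def test_determinism(self):
        courses = w.generate_timecourse_dataset(n_genes=5, rng_seed=12)
        kw = dict(methods=["hsic:laplace"], noise=w.NoiseConfig(n_samples=100, rng_seed=13),
                  a_seed=14)
        r1, log1 = w.deviation_experiment(courses, **kw)
        r2, log2 = w.deviation_experiment(courses, **kw)
        assert r1.equals(r2) and log1 == log2

    def test_hsic_indices_invariant_to_per_gene_affine_scaling(self):
        """Per-gene monotone (affine) rescaling of the factor columns does
        not move the HSIC indices: the median-heuristic bandwidth scales
        with the data and rbf/laplace kernels are translation-invariant.
        This is the mechanism behind scaled and non-scaled runs ranking
        genes consistently."""
        rng = np.random.default_rng(15)
        X = rng.normal(size=(200, 5)) * rng.uniform(0.5, 3.0, 5)
        u = np.sin(X[:, 0]) + 0.3 * rng.normal(size=200)
        lo, hi = X.min(axis=0), X.max(axis=0)
        X_scaled = (X - lo) / (hi - lo)
        for fam in ("rbf", "laplace"):
            spec = w.KernelSpec(fam)
            raw = [e.value for e in w.hsic_indices_matrix(X, u, spec)]
            scl = [e.value for e in w.hsic_indices_matrix(X_scaled, u, spec)]
            assert scl == pytest.approx(raw, abs=1e-8)
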