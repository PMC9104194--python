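import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from maglevlab.stats import (
    Cohort,
    ConfusionCounts,
    blind_validation,
    classify,
    confidence_ellipse,
    ellipse_overlap_area,
    lda_fit,
    metrics,
    pairwise_pvalue_matrix,
    powerlaw_exponent,
    student_t,
)


def gaussian_cohort(rng, means, n_per_class=20, cov=None, prefix=""):
    cov = np.eye(2) if cov is None else np.asarray(cov)
    pts, labels, ids = [], [], []
    for name, mu in means.items():
        draws = rng.multivariate_normal(mu, cov, size=n_per_class)
        pts.append(draws)
        labels += [name] * n_per_class
        ids += [f"{prefix}{name}-{i}" for i in range(n_per_class)]
    return Cohort(np.vstack(pts), np.array(labels), np.array(ids))


@pytest.fixture
def two_class(rng):
    return gaussian_cohort(rng, {"NOP": (0.0, 0.0), "PDAC": (6.0, 0.0)})


class TestCohort:
    def test_duplicate_donors_rejected(self):
        with pytest.raises(ValueError, match="donor"):
            Cohort(np.zeros((2, 2)), np.array(["a", "b"]), np.array(["d1", "d1"]))

    def test_frame_round_trip(self, two_class):
        again = Cohort.from_frame(two_class.to_frame())
        np.testing.assert_array_equal(again.points, two_class.points)


class TestLdaFit:
    def test_symmetric_classes_boundary_is_y_axis(self):
        rng = np.random.default_rng(1234)
        n = 500
        pts = rng.multivariate_normal((3.0, 0.0), np.eye(2), n)
        cohort = Cohort(
            np.vstack([-pts, pts]),
            np.array(["NOP"] * n + ["PDAC"] * n),
            np.array([f"d{i}" for i in range(2 * n)]),
        )
        model = lda_fit(cohort, "PDAC")
        # boundary w.x = t passes through the origin, w along x
        assert model.threshold == pytest.approx(0.0, abs=1e-9)
        assert abs(model.weight_vector[1]) < 0.1 * abs(model.weight_vector[0])

    def test_isotropic_covariance_w_along_mean_difference(self):
        rng = np.random.default_rng(7)
        base = rng.multivariate_normal((0, 0), np.eye(2), 400)
        shift = np.array([2.0, 1.0])
        cohort = Cohort(
            np.vstack([base[:200], base[200:] + shift]),
            np.array(["NOP"] * 200 + ["PDAC"] * 200),
            np.array([f"d{i}" for i in range(400)]),
        )
        model = lda_fit(cohort, "PDAC")
        w = model.weight_vector / np.linalg.norm(model.weight_vector)
        expected = shift / np.linalg.norm(shift)
        assert abs(np.dot(w, expected)) > 0.98

    def test_matches_projection_grid_search(self, rng):
        """Oracle: Fisher criterion maximized by brute-force direction scan."""
        for trial in range(5):
            cohort = gaussian_cohort(
                rng,
                {"NOP": (0.0, 0.0), "PDAC": tuple(rng.uniform(1, 3, 2))},
                n_per_class=25,
                cov=[[2.0, 0.7], [0.7, 1.0]],
                prefix=f"t{trial}",
            )
            x0 = cohort.points[cohort.labels == "NOP"]
            x1 = cohort.points[cohort.labels == "PDAC"]

            def fisher_j(w):
                p0, p1 = x0 @ w, x1 @ w
                pooled = (
                    (len(p0) - 1) * p0.var(ddof=1) + (len(p1) - 1) * p1.var(ddof=1)
                ) / (len(p0) + len(p1) - 2)
                return (p1.mean() - p0.mean()) ** 2 / pooled

            best = max(
                fisher_j(np.array([np.cos(t), np.sin(t)]))
                for t in np.linspace(0, np.pi, 3600, endpoint=False)
            )
            w = lda_fit(cohort, "PDAC").weight_vector
            j_lda = fisher_j(w / np.linalg.norm(w))
            assert j_lda >= best * 0.99

    def test_too_few_points(self):
        cohort = Cohort(
            np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]),
            np.array(["NOP", "NOP", "PDAC"]),
            np.array(["a", "b", "c"]),
        )
        with pytest.raises(ValueError):
            lda_fit(cohort, "PDAC")

    def test_singular_covariance_ridge_warns(self):
        pts = np.array(
            [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [5.0, 0.0], [6.0, 0.0], [7.0, 0.0]]
        )
        cohort = Cohort(
            pts,
            np.array(["NOP"] * 3 + ["PDAC"] * 3),
            np.array([f"d{i}" for i in range(6)]),
        )
        with pytest.warns(UserWarning, match="ridge"):
            model = lda_fit(cohort, "PDAC")
        assert np.all(np.isfinite(model.weight_vector))

    def test_boundary_invariant_under_common_rescaling(self, two_class):
        model = lda_fit(two_class, "PDAC")
        scale = np.array([3.0, 0.5])
        scaled = Cohort(two_class.points * scale, two_class.labels, two_class.donor_ids)
        model2 = lda_fit(scaled, "PDAC")
        pred1 = classify(model, two_class.points)
        pred2 = classify(model2, scaled.points)
        np.testing.assert_array_equal(pred1, pred2)


class TestClassifyAndMetrics:
    def test_class_means_classified_correctly(self, two_class):
        model = lda_fit(two_class, "PDAC")
        mu0 = two_class.points[two_class.labels == "NOP"].mean(axis=0)
        mu1 = two_class.points[two_class.labels == "PDAC"].mean(axis=0)
        assert classify(model, np.array([mu0]))[0] == "NOP"
        assert classify(model, np.array([mu1]))[0] == "PDAC"

    def test_counts_partition_cohort(self, two_class):
        model = lda_fit(two_class, "PDAC")
        _, counts = classify(model, two_class.points, two_class.labels)
        assert counts.total == len(two_class)

    def test_six_sigma_separation_perfect(self, rng):
        # Gaussian tail oracle: P(misclassification) ~ Phi(-3) ~ 1.3e-3;
        # 100 points -> expected errors ~ 0.13, so demand zero on this seed
        cohort = gaussian_cohort(
            rng, {"NOP": (0.0, 0.0), "PDAC": (6.0, 0.0)}, n_per_class=50
        )
        model = lda_fit(cohort, "PDAC")
        _, counts = classify(model, cohort.points, cohort.labels)
        assert counts.false_positive == 0 and counts.false_negative == 0
        assert metrics(counts)["accuracy"] == 1.0

    def test_metrics_paper_caption_ratios(self):
        # 15 + 15 cohort, one error per class
        m = metrics(ConfusionCounts(14, 1, 1, 14))
        assert m["specificity"] == pytest.approx(14 / 15)
        assert m["sensitivity"] == pytest.approx(14 / 15)
        assert m["accuracy"] == pytest.approx(28 / 30)

    def test_metrics_breast_cancer_narrative(self):
        # specificity 93%, 40% of 5 cancer patients misclassified -> 85% accuracy
        m = metrics(ConfusionCounts(14, 1, 2, 3))
        assert m["specificity"] == pytest.approx(0.9333, abs=1e-4)
        assert m["sensitivity"] == pytest.approx(0.60)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(10, 0, 0, 10))
        assert m == {"specificity": 1.0, "sensitivity": 1.0, "accuracy": 1.0}

    def test_zero_denominator_flagged_none(self):
        m = metrics(ConfusionCounts(5, 1, 0, 0))
        assert m["sensitivity"] is None
        assert m["specificity"] is not None

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    @settings(max_examples=200, deadline=None)
    def test_accuracy_identity(self, tn, fp, fn, tp):
        c = ConfusionCounts(tn, fp, fn, tp)
        m = metrics(c)
        n_neg, n_pos = tn + fp, tp + fn
        if n_neg > 0 and n_pos > 0:
            assert m["accuracy"] == pytest.approx(
                (m["specificity"] * n_neg + m["sensitivity"] * n_pos)
                / (n_neg + n_pos)
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestStudentT:
    def test_identical_groups(self):
        res = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_large_shift_small_p(self):
        res = student_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res["p"] < 1e-3

    def test_matches_reference_implementation(self, rng):
        for _ in range(100):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            ours = student_t(a, b)
            ref_t, ref_p = sps.ttest_ind(a, b, equal_var=True)
            assert ours["t"] == pytest.approx(ref_t, abs=1e-10)
            assert ours["p"] == pytest.approx(ref_p, abs=1e-10)

    def test_degenerate_zero_variance(self):
        same = student_t([2.0, 2.0], [2.0, 2.0])
        assert same["p"] == 1.0 and same["degenerate"]
        diff = student_t([2.0, 2.0], [3.0, 3.0])
        assert diff["p"] == 0.0 and diff["degenerate"]

    def test_too_small_groups(self):
        with pytest.raises(ValueError):
            student_t([1.0], [1.0, 2.0])


class TestPvalueMatrix:
    def test_identical_distributions_entry(self):
        pts = np.array([[1.0, 0], [2.0, 0], [3.0, 0], [1.0, 0], [2.0, 0], [3.0, 0]])
        cohort = Cohort(
            pts,
            np.array(["A"] * 3 + ["B"] * 3),
            np.array([f"d{i}" for i in range(6)]),
        )
        mat = pairwise_pvalue_matrix(cohort)
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, rng):
        cohort = gaussian_cohort(
            rng, {"A": (0, 0), "B": (1, 0), "C": (2, 0)}, n_per_class=8
        )
        mat = pairwise_pvalue_matrix(cohort)
        np.testing.assert_array_equal(mat.values, mat.values.T)
        np.testing.assert_array_equal(np.diag(mat.values), 1.0)

    def test_shifted_class_has_minimal_row(self, rng):
        cohort = gaussian_cohort(
            rng,
            {"A": (0, 0), "B": (0.1, 0), "C": (4.0, 0)},  # C shifted 4 sigma
            n_per_class=15,
        )
        mat = pairwise_pvalue_matrix(cohort)
        off_diag = mat.values[~np.eye(3, dtype=bool)]
        # the shifted class owns the smallest p-values
        assert mat.loc["C"].drop("C").min() == off_diag.min()
        assert mat.loc["C"].drop("C").max() < mat.loc["A", "B"]

    def test_bonferroni_scales_raw_pvalues(self, rng):
        cohort = gaussian_cohort(
            rng, {"A": (0, 0), "B": (1.0, 0), "C": (2.0, 0)}, n_per_class=10
        )
        raw = pairwise_pvalue_matrix(cohort)
        adj = pairwise_pvalue_matrix(cohort, bonferroni=True)
        np.testing.assert_allclose(
            adj.values, np.minimum(raw.values * 3, 1.0), rtol=1e-12
        )


class TestConfidenceEllipse:
    def test_isotropic_radius_closed_form(self, rng):
        sigma = 2.0
        pts = rng.multivariate_normal((0, 0), sigma**2 * np.eye(2), 200_000)
        e = confidence_ellipse(pts, level=0.95)
        expected = sigma * np.sqrt(sps.chi2.ppf(0.95, 2))
        assert e.semi_axes[0] == pytest.approx(expected, rel=0.02)
        assert e.semi_axes[1] == pytest.approx(expected, rel=0.02)

    def test_rotation_equivariance(self, rng):
        pts = rng.multivariate_normal((0, 0), [[4.0, 0], [0, 1.0]], 500)
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts @ rot.T)
        assert e2.orientation == pytest.approx(e1.orientation + theta, abs=0.02)
        np.testing.assert_allclose(e2.semi_axes, e1.semi_axes, rtol=1e-9)

    def test_monte_carlo_coverage(self, rng):
        # oracle: 95% ellipse from the true covariance covers 95% of draws
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        pts = rng.multivariate_normal((1.0, -1.0), cov, 100_000)
        e = confidence_ellipse(pts, level=0.95)
        d = pts - e.center
        c, s = np.cos(e.orientation), np.sin(e.orientation)
        rot = np.array([[c, s], [-s, c]])
        local = d @ rot.T
        inside = (local[:, 0] / e.semi_axes[0]) ** 2 + (
            local[:, 1] / e.semi_axes[1]
        ) ** 2 <= 1.0
        assert inside.mean() == pytest.approx(0.95, abs=0.01)

    def test_degenerate_flagged(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        e = confidence_ellipse(pts)
        assert e.degenerate

    def test_overlap_area_identical_is_own_area(self, rng):
        pts = rng.multivariate_normal((0, 0), np.eye(2), 300)
        e = confidence_ellipse(pts)
        area = ellipse_overlap_area(e, e)
        analytic = np.pi * e.semi_axes[0] * e.semi_axes[1]
        assert area == pytest.approx(analytic, rel=0.01)

    def test_disjoint_ellipses_zero_overlap(self, rng):
        pts = rng.multivariate_normal((0, 0), 0.01 * np.eye(2), 300)
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts + np.array([100.0, 0.0]))
        assert ellipse_overlap_area(e1, e2) == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))


class TestBlindValidation:
    def test_same_distribution_perfect(self, rng, two_class):
        model = lda_fit(two_class, "PDAC")
        holdout = gaussian_cohort(
            rng, {"NOP": (0.0, 0.0), "PDAC": (6.0, 0.0)}, n_per_class=5, prefix="ho-"
        )
        res = blind_validation(model, holdout, two_class.donor_ids)
        assert res["metrics"]["accuracy"] == 1.0
        assert "model" in res["provenance"]

    def test_donor_overlap_rejected(self, two_class):
        model = lda_fit(two_class, "PDAC")
        with pytest.raises(ValueError, match="overlap"):
            blind_validation(model, two_class, two_class.donor_ids)

    def test_empty_holdout_class_flagged(self, rng, two_class):
        model = lda_fit(two_class, "PDAC")
        holdout = gaussian_cohort(
            rng, {"NOP": (0.0, 0.0)}, n_per_class=5, prefix="ho-"
        )
        res = blind_validation(model, holdout, two_class.donor_ids)
        assert res["metrics"]["sensitivity"] is None


class TestPowerLaw:
    def test_exact_inverse_square(self):
        q = np.logspace(-1, 0, 50)
        fit = powerlaw_exponent(q, q**-2.0)
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-10)

    def test_amplitude_invariance(self):
        q = np.logspace(-1, 0, 50)
        f1 = powerlaw_exponent(q, q**-3.0)
        f2 = powerlaw_exponent(q, 42.0 * q**-3.0)
        assert f1.exponent == pytest.approx(f2.exponent, abs=1e-12)
        assert f2.exponent == pytest.approx(3.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        q = np.linspace(-0.1, 1, 10)
        with pytest.raises(ValueError):
            powerlaw_exponent(q, np.ones(10))

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        q = np.logspace(-1, 0, 80)
        intensity = q**-2.01 * rng.lognormal(0, 0.02, 80)
        fit = powerlaw_exponent(q, intensity)
        x = sm.add_constant(np.log(q))
        res = sm.OLS(np.log(intensity), x).fit()
        assert fit.exponent == pytest.approx(-res.params[1], abs=1e-10)
        assert fit.stderr == pytest.approx(res.bse[1], abs=1e-10)


class TestAgainstSklearn:
    def test_lda_predictions_match_sklearn(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        cohort = gaussian_cohort(
            rng,
            {"NOP": (0.0, 0.0), "PDAC": (1.5, 0.5)},
            n_per_class=40,
            cov=[[1.5, 0.4], [0.4, 0.8]],
        )
        model = lda_fit(cohort, "PDAC")
        ours = classify(model, cohort.points)
        sk = LinearDiscriminantAnalysis(solver="svd", priors=[0.5, 0.5])
        sk.fit(cohort.points, cohort.labels)
        theirs = sk.predict(cohort.points)
        agree = np.mean(ours == theirs)
        assert agree >= 0.975  # covariance estimator conventions differ slightly
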