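import numpy as np
import pytest
from scipy import linalg

from isomigrate import (
    EllipseModel,
    FeatherRecord,
    bayesian_sea,
    ellipse_overlap_pct,
    fit_ellipse,
    lda_scores,
    pairwise_niche_overlap,
    sea,
    seac,
)


def unit_circle_ellipse(cx=0.0, cy=0.0, n=100):
    return EllipseModel(mean=[cx, cy], cov=np.eye(2), n=n)


class TestFitEllipse:
    def test_hand_computed_covariance(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        e = fit_ellipse(pts)
        assert np.allclose(e.mean, [1 / 3, 1 / 3])
        assert np.allclose(e.cov, [[1 / 3, -1 / 6], [-1 / 6, 1 / 3]])

    def test_collinear_points_rejected(self):
        pts = np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 5.0], [1.0, -3.0]])
        with pytest.raises(ValueError, match="rank"):
            fit_ellipse(pts)

    def test_covariance_transforms_as_a_sigma_at(self, rng):
        pts = rng.normal(size=(40, 2))
        A = np.array([[2.0, 0.7], [-0.3, 1.4]])
        e = fit_ellipse(pts)
        e2 = fit_ellipse(pts @ A.T)
        assert np.allclose(e2.cov, A @ e.cov @ A.T)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestEllipseAreas:
    def test_identity_covariance_area_is_pi(self):
        assert sea(unit_circle_ellipse()) == pytest.approx(np.pi)

    def test_diag_4_1_area_is_two_pi(self):
        e = EllipseModel(mean=[0, 0], cov=np.diag([4.0, 1.0]), n=10)
        assert sea(e) == pytest.approx(2 * np.pi)

    def test_seac_small_sample_factor(self):
        e = unit_circle_ellipse(n=3)
        assert seac(e) == pytest.approx(2 * sea(e))
        e50 = unit_circle_ellipse(n=50)
        assert seac(e50) / sea(e50) == pytest.approx(49 / 48)

    def test_rotation_invariance_and_determinant_scaling(self, rng):
        pts = rng.normal(size=(60, 2)) @ np.array([[3.0, 1.0], [0.0, 0.5]])
        t = 0.7
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        assert sea(fit_ellipse(pts @ R.T)) == pytest.approx(sea(fit_ellipse(pts)))
        A = np.array([[2.0, 1.0], [0.5, 3.0]])
        assert sea(fit_ellipse(pts @ A.T)) == pytest.approx(
            abs(np.linalg.det(A)) * sea(fit_ellipse(pts))
        )


class TestBayesianSea:
    def test_posterior_concentrates_on_true_sea(self, rng):
        cov = np.array([[9.0, 2.0], [2.0, 4.0]])
        pts = rng.multivariate_normal([0, 0], cov, size=500)
        draws = bayesian_sea(pts, n_draws=4000, seed=0)
        ml = sea(fit_ellipse(pts))
        assert abs(np.median(draws) - ml) / ml < 0.05

    def test_reproducible_under_seed(self, rng):
        pts = rng.normal(size=(30, 2))
        assert np.array_equal(bayesian_sea(pts, 100, seed=5), bayesian_sea(pts, 100, seed=5))

    def test_zero_draws_errors(self, rng):
        with pytest.raises(ValueError):
            bayesian_sea(rng.normal(size=(10, 2)), n_draws=0)

    def test_credible_interval_covers_generating_sea(self):
        """95% CI covers the generating covariance's SEA in >= 90% of reps."""
        gen_cov = np.array([[4.0, 1.0], [1.0, 2.0]])
        true_sea = np.pi * np.sqrt(np.linalg.det(gen_cov))
        ss = np.random.SeedSequence(2024)
        hits = 0
        for rep_seed in ss.spawn(50):
            rng = np.random.default_rng(rep_seed)
            pts = rng.multivariate_normal([0, 0], gen_cov, size=100)
            draws = bayesian_sea(pts, n_draws=1000, seed=rep_seed)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            hits += lo <= true_sea <= hi
        assert hits >= 45


class TestOverlap:
    def test_identical_ellipses_100_percent(self, rng):
        pts = rng.normal(size=(50, 2))
        e = fit_ellipse(pts)
        assert ellipse_overlap_pct(e, e) == pytest.approx(100.0, abs=1.0)

    def test_distant_ellipses_zero(self):
        a = unit_circle_ellipse(0.0, 0.0)
        b = unit_circle_ellipse(10.0, 0.0)
        assert ellipse_overlap_pct(a, b) == 0.0

    def test_unit_circles_lens_closed_form(self):
        """Circles of radius 1 with centers 1 apart: lens area 2π/3 − √3/2."""
        a = unit_circle_ellipse(0.0, 0.0)
        b = unit_circle_ellipse(1.0, 0.0)
        lens = 2 * np.pi / 3 - np.sqrt(3) / 2
        expected = 100.0 * lens / (2 * np.pi - lens)
        got = ellipse_overlap_pct(a, b)
        assert got == pytest.approx(expected, rel=0.01)

    def test_symmetry(self, rng):
        e1 = fit_ellipse(rng.normal(size=(30, 2)))
        e2 = fit_ellipse(rng.normal(loc=1.0, size=(30, 2)))
        assert ellipse_overlap_pct(e1, e2) == pytest.approx(ellipse_overlap_pct(e2, e1))

    def test_min_denominator_at_least_union(self, rng):
        e1 = fit_ellipse(rng.normal(size=(30, 2)))
        e2 = fit_ellipse(rng.normal(loc=0.5, scale=2.0, size=(30, 2)))
        union = ellipse_overlap_pct(e1, e2)
        mino = ellipse_overlap_pct(e1, e2, denominator="min")
        assert mino >= union


def _labelled_cloud(rng, centers, n=10):
    records, labels = [], []
    for ci, (label, center) in enumerate(centers.items()):
        pts = rng.normal(loc=center, scale=1.0, size=(n, 4))
        for i, p in enumerate(pts):
            records.append(
                FeatherRecord(
                    id=f"{label}_{i}", species="BARS", site=label, population=label,
                    sex="M", d2h_f=p[0], d13c_f=p[1], d15n_f=p[2], wing_mm=abs(p[3]) + 100,
                )
            )
            labels.append(label)
    return records, labels


class TestLdaScores:
    def test_separated_classes_have_disjoint_score_ranges(self, rng):
        records, labels = _labelled_cloud(
            rng, {"A": [-60, -20, 10, 15], "B": [-40, -20, 10, 15]}, n=15
        )
        scores, used = lda_scores(records, labels)
        a = scores[np.array(labels)[used] == "A", 0]
        b = scores[np.array(labels)[used] == "B", 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_matches_generalized_eigenproblem_oracle(self, rng):
        """Brute-force Fisher directions: eig(Sw⁻¹ Sb) up to sign/scale."""
        records, labels = _labelled_cloud(
            rng, {"A": [-60, -22, 10, 12], "B": [-50, -18, 11, 18], "C": [-45, -20, 13, 14]},
            n=4,
        )
        scores, used = lda_scores(records, labels)
        X = np.array([
            [r.d2h_f, r.d13c_f, r.d15n_f, r.wing_mm] for i, r in enumerate(records)
            if i in used
        ])
        y = np.array(labels)[used]
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        classes = np.unique(y)
        Sw = sum(
            np.cov(X[y == c], rowvar=False, ddof=1) * ((y == c).sum() - 1) for c in classes
        ) / (len(y) - len(classes))
        means = np.array([X[y == c].mean(axis=0) for c in classes])
        grand = X.mean(axis=0)
        Sb = sum(
            (y == c).sum() * np.outer(m - grand, m - grand) for c, m in zip(classes, means)
        ) / (len(classes) - 1)
        vals, vecs = linalg.eigh(Sb, Sw)
        directions = vecs[:, np.argsort(vals)[::-1][:2]]
        oracle = X @ directions
        for j in range(2):
            r = np.corrcoef(scores[:, j], oracle[:, j])[0, 1]
            assert abs(r) > 1 - 1e-8

    def test_single_class_errors(self, rng):
        records, labels = _labelled_cloud(rng, {"A": [0, 0, 0, 10]}, n=6)
        with pytest.raises(ValueError, match="two classes"):
            lda_scores(records, labels)

    def test_collinear_variables_rejected(self, rng):
        records, labels = _labelled_cloud(rng, {"A": [0, 0, 0, 10], "B": [5, 0, 0, 10]}, n=6)
        # duplicate the d2h axis by passing it twice
        with pytest.raises(ValueError, match="singular|collinear"):
            lda_scores(records, labels, variables=("d2h_f", "d2h_f", "d13c_f"))

    def test_incomplete_cases_dropped(self, rng):
        records, labels = _labelled_cloud(rng, {"A": [0, 0, 0, 10], "B": [9, 0, 0, 10]}, n=6)
        import dataclasses
        records[0] = dataclasses.replace(records[0], wing_mm=None)
        scores, used = lda_scores(records, labels)
        assert 0 not in used
        assert scores.shape == (len(records) - 1, 2)


class TestPairwiseNicheOverlap:
    def test_same_distribution_overlaps_heavily(self, rng):
        records, _ = _labelled_cloud(rng, {"A": [-55, -20, 10, 15], "B": [-55, -20, 10, 15]},
                                     n=200)
        out = pairwise_niche_overlap(records, axes=("d2h_f", "d13c_f"), n_draws=500, seed=0)
        assert out.loc[0, "overlap_pct"] > 50.0

    def test_distant_groups_do_not_overlap(self, rng):
        records, _ = _labelled_cloud(rng, {"A": [-80, -30, 10, 15], "B": [-40, -10, 10, 15]},
                                     n=30)
        out = pairwise_niche_overlap(records, axes=("d2h_f", "d13c_f"), n_draws=200, seed=0)
        assert out.loc[0, "overlap_pct"] == 0.0

    def test_duplicated_group_is_identical(self, rng):
        records, _ = _labelled_cloud(rng, {"A": [-55, -20, 10, 15]}, n=40)
        import dataclasses
        clones = [dataclasses.replace(r, id=r.id + "c", population="B") for r in records]
        out = pairwise_niche_overlap(records + clones, axes=("d2h_f", "d13c_f"),
                                     n_draws=200, seed=0)
        assert out.loc[0, "overlap_pct"] == pytest.approx(100.0, abs=1.0)
        assert out.loc[0, "sea_1"] == pytest.approx(out.loc[0, "sea_2"])

    def test_undersized_group_dropped_with_warning(self, rng):
        records, _ = _labelled_cloud(
            rng, {"A": [-55, -20, 10, 15], "B": [-45, -18, 10, 15]}, n=20
        )
        import dataclasses
        tiny = [dataclasses.replace(records[0], id="t1", population="C"),
                dataclasses.replace(records[1], id="t2", population="C")]
        with pytest.warns(UserWarning, match="'C'"):
            out = pairwise_niche_overlap(records + tiny, axes=("d2h_f", "d13c_f"),
                                         n_draws=100, seed=0)
        assert set(out["group_1"]) | set(out["group_2"]) == {"A", "B"}

    def test_lda_axes_end_to_end(self, rng):
        # three groups so two discriminant functions span the score plane
        records, _ = _labelled_cloud(
            rng,
            {"A": [-70, -24, 9, 12], "B": [-40, -16, 12, 20], "C": [-55, -20, 15, 30]},
            n=25,
        )
        out = pairwise_niche_overlap(records, axes="lda", n_draws=100, seed=0)
        ab = out[(out.group_1 == "A") & (out.group_2 == "B")].iloc[0]
        assert ab["overlap_pct"] < 5.0
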