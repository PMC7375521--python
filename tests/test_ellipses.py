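"""Convex hulls, standard ellipse areas, Bayesian posteriors, and overlap."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isofox import Period, datasets
from isofox.ellipses import (EllipseSpec, StandardEllipse, bayesian_sea,
                             convex_hull_area, ellipse_overlap, sea_corrected,
                             standard_ellipse_area)
from isofox.niches import group_from_points

# the six Middle-Palaeolithic high-niche fox coordinates from the packaged table
MP_HIGH = np.array([(-19.7, 10.0), (-20.2, 7.8), (-20.4, 8.2),
                    (-20.1, 9.0), (-20.3, 8.4), (-19.9, 8.6)])

# the five Gravettian high-niche fox coordinates
G_HIGH = np.array([(-20.1, 8.7), (-20.3, 7.6), (-19.7, 7.1),
                   (-19.7, 9.7), (-20.3, 9.2)])


def mc_hull_area(points, n=1_000_000, seed=0):
    """Rejection-sampling oracle for the convex hull area."""
    from scipy.spatial import Delaunay

    pts = np.asarray(points)
    lo, hi = pts.min(0), pts.max(0)
    rng = np.random.default_rng(seed)
    u = rng.uniform(lo, hi, size=(n, 2))
    inside = Delaunay(pts).find_simplex(u) >= 0
    return inside.mean() * np.prod(hi - lo)


def mc_ellipse_overlap(a: EllipseSpec, b: EllipseSpec, n=1_000_000, seed=0):
    """Rejection-sampling oracle for the ellipse intersection area.

    Returns (estimate, standard error)."""
    box_lo = np.minimum(a.boundary(256).min(0), b.boundary(256).min(0))
    box_hi = np.maximum(a.boundary(256).max(0), b.boundary(256).max(0))
    rng = np.random.default_rng(seed)
    u = rng.uniform(box_lo, box_hi, size=(n, 2))

    def inside(e, pts):
        d = pts - e.center
        m = np.linalg.inv(e.scale * e.shape)
        return np.einsum("ij,jk,ik->i", d, m, d) <= 1.0

    hits = inside(a, u) & inside(b, u)
    box = np.prod(box_hi - box_lo)
    p = hits.mean()
    return p * box, box * np.sqrt(p * (1 - p) / n)


class TestConvexHull:
    def test_mp_high_fox_total_area(self):
        assert convex_hull_area(MP_HIGH) == pytest.approx(0.46, abs=0.005)

    def test_right_triangle(self):
        assert convex_hull_area([(0, 0), (1, 0), (0, 1)]) == pytest.approx(0.5)

    def test_matches_monte_carlo_oracle(self, rng):
        pts = rng.normal(size=(20, 2))
        area = convex_hull_area(pts)
        assert area == pytest.approx(mc_hull_area(pts), rel=0.01)

    @pytest.mark.parametrize("pts", [
        [(0, 0), (1, 1)],
        [(0, 0), (1, 1), (2, 2), (3, 3)],  # collinear
    ])
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(ValueError):
            convex_hull_area(pts)

    def test_hull_contains_all_points(self, rng):
        from shapely.geometry import MultiPoint, Point
        pts = rng.normal(size=(15, 2))
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        assert convex_hull_area(pts) == pytest.approx(hull.area, rel=1e-9)
        assert all(hull.buffer(1e-9).contains(Point(*p)) for p in pts)


class TestStandardEllipseArea:
    def test_mp_high_fox_sea(self):
        assert standard_ellipse_area(MP_HIGH) == pytest.approx(0.3756, abs=5e-4)

    def test_gravettian_high_fox_sea(self):
        assert standard_ellipse_area(G_HIGH) == pytest.approx(1.036, abs=1e-3)

    def test_identity_covariance_gives_pi(self):
        # four points whose sample covariance is exactly the identity
        pts = np.array([(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)]) * np.sqrt(3 / 2)
        np.testing.assert_allclose(np.cov(pts.T, ddof=1), np.eye(2), atol=1e-12)
        assert standard_ellipse_area(pts) == pytest.approx(np.pi)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            standard_ellipse_area(np.array([(0, 0), (1, 1), (2, 2)], dtype=float))

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(0, 2 * np.pi))
    @settings(deadline=None, max_examples=40)
    def test_translation_and_rotation_invariant(self, dx, dy, theta):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        base = standard_ellipse_area(pts)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [dx, dy]
        assert standard_ellipse_area(moved) == pytest.approx(base, rel=1e-8)

    @given(st.floats(0.1, 10))
    @settings(deadline=None, max_examples=30)
    def test_quadratic_scaling(self, c):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 2))
        assert standard_ellipse_area(pts * c) == pytest.approx(
            c ** 2 * standard_ellipse_area(pts), rel=1e-8)


class TestSeaCorrected:
    def test_mp_high_fox_seac(self):
        assert sea_corrected(0.3756, 6) == pytest.approx(0.4695, abs=5e-4)

    def test_factor_two_at_n_3(self):
        assert sea_corrected(np.pi, 3) == pytest.approx(2 * np.pi)

    def test_ratio_tends_to_one(self):
        assert sea_corrected(1.0, 10_000) == pytest.approx(1.0, abs=1e-3)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            sea_corrected(1.0, 2)


class TestBayesianSea:
    def test_posterior_matches_chi_square_decomposition_oracle(self):
        # Independent oracle for the conjugate posterior: if Σ ~ IW(ν, Λ)
        # then det(Σ) = det(Λ) / det(W) with W ~ Wishart(ν, I), whose
        # determinant is a product of independent χ²_ν · χ²_{ν−1} draws
        # (Bartlett decomposition).  The area posterior median from
        # scipy's invwishart sampler must agree with that construction,
        # and the posterior must bracket the ML estimate 0.38.
        from scipy.stats import chi2
        g = group_from_points("mp_high", MP_HIGH)
        draws = bayesian_sea(g, 40_000, seed=5)
        nu_n = 3 + g.n
        lam = 1e-3 * np.eye(2) + g.cov * (g.n - 1)
        rng = np.random.default_rng(123)
        det_w = chi2.rvs(nu_n, size=40_000, random_state=rng) * \
            chi2.rvs(nu_n - 1, size=40_000, random_state=rng)
        oracle = np.pi * np.sqrt(np.linalg.det(lam) / det_w)
        assert np.median(draws) == pytest.approx(np.median(oracle), rel=0.03)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo < 0.38 < hi

    def test_posterior_concentrates_for_large_n(self, rng):
        sigma = np.array([[1.0, 0.3], [0.3, 0.8]])
        pts = rng.multivariate_normal([0, 0], sigma, size=2000)
        truth = np.pi * np.sqrt(np.linalg.det(np.cov(pts.T, ddof=1)))
        draws = bayesian_sea(group_from_points("big", pts), 4000, seed=6)
        assert np.median(draws) == pytest.approx(truth, rel=0.05)

    def test_same_seed_reproduces_draws(self, mp_high_fox_points):
        g = group_from_points("mp", mp_high_fox_points)
        a = bayesian_sea(g, 500, seed=42)
        b = bayesian_sea(g, 500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_draws_rejected(self):
        with pytest.raises(ValueError):
            bayesian_sea(group_from_points("mp", MP_HIGH), 0)


class TestOverlap:
    def test_identical_ellipses_full_overlap(self):
        e = EllipseSpec(np.array([0.0, 0.0]), np.array([[2.0, 0.5], [0.5, 1.0]]))
        ov = ellipse_overlap(e, e)
        assert ov.area == pytest.approx(e.area, rel=1e-3)
        assert ov.pct_of_a == pytest.approx(100.0, abs=0.1)
        assert ov.pct_of_b == pytest.approx(100.0, abs=0.1)

    def test_disjoint_ellipses(self):
        a = EllipseSpec(np.array([0.0, 0.0]), np.eye(2))
        b = EllipseSpec(np.array([100.0, 0.0]), np.eye(2))
        assert ellipse_overlap(a, b).area == 0.0

    def test_symmetric_in_area(self, rng):
        for _ in range(5):
            a = _random_ellipse(rng)
            b = _random_ellipse(rng)
            assert ellipse_overlap(a, b).area == pytest.approx(
                ellipse_overlap(b, a).area, abs=1e-6)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            EllipseSpec(np.zeros(2), np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_fixture_overlap_matches_published_table(self, mp_high_fox_points):
        carn = StandardEllipse().fit(
            datasets.large_carnivore_group(Period.MP).points)
        fox = StandardEllipse().fit(mp_high_fox_points)
        assert fox.seac_ == pytest.approx(0.47, abs=0.005)
        assert carn.seac_ == pytest.approx(1.69, abs=0.01)
        ov = carn.overlap(fox)
        assert ov.area == pytest.approx(0.23, abs=0.02)
        assert ov.pct_of_b == pytest.approx(49.6, abs=2.0)


def _random_ellipse(rng):
    a = rng.normal(size=(2, 2))
    shape = a @ a.T + 0.2 * np.eye(2)
    return EllipseSpec(rng.normal(scale=1.5, size=2), shape,
                       scale=float(rng.uniform(0.5, 2.0)))


class TestStandardEllipseEstimator:
    def test_published_seac_values_per_period(self, carnivores):
        expected = {Period.MP: (0.38, 0.47), Period.AURIGNACIAN: (0.83, 0.89),
                    Period.GRAVETTIAN: (1.04, 1.38)}
        for period, (sea, seac) in expected.items():
            pts = datasets.fox_niche_points("high", period)
            est = StandardEllipse().fit(pts)
            assert round(est.sea_, 2) == sea
            assert round(est.seac_, 2) == seac

    def test_seac_exceeds_sea(self, mp_high_fox_points):
        est = StandardEllipse().fit(mp_high_fox_points)
        assert est.seac_ == pytest.approx(est.sea_ * 5 / 4)

    def test_sklearn_params_roundtrip(self):
        est = StandardEllipse(prior_df=4.0)
        assert StandardEllipse(**est.get_params()).prior_df == 4.0

    def test_requires_fit_before_ellipse(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            StandardEllipse().ellipse()
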