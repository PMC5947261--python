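"""Niche-ellipse geometry: areas, boundaries, unions, RINI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoniche import geometry

# For 2 degrees of freedom the chi-square CDF is 1 − exp(−q/2), so the
# p-level quantile has the closed form q = −2·ln(1 − p): an oracle that is
# independent of scipy's generic quantile machinery.
Q95 = -2.0 * math.log(0.05)
AREA95_IDENTITY = math.pi * Q95


def _random_spd(rng, scale=1.0):
    a = rng.normal(size=(2, 2))
    return a @ a.T * scale + np.eye(2) * 1e-3


class TestFitMeanCovariance:
    def test_hand_computed_square(self):
        mean, cov = geometry.fit_mean_covariance([(0, 0), (1, 0), (0, 1), (1, 1)])
        np.testing.assert_allclose(mean, [0.5, 0.5])
        np.testing.assert_allclose(cov, np.diag([1 / 3, 1 / 3]))

    def test_two_points_insufficient(self):
        with pytest.raises(geometry.InsufficientDataError):
            geometry.fit_mean_covariance([(0, 0), (1, 1)])

    def test_collinear_points_degenerate(self):
        pts = [(i, 2.0 * i + 1.0) for i in range(5)]
        with pytest.raises(geometry.DegenerateGeometryError):
            geometry.fit_mean_covariance(pts)


class TestPredictionEllipseArea:
    def test_identity_covariance_matches_closed_form(self):
        area = geometry.prediction_ellipse_area(np.eye(2), 0.95)
        assert area == pytest.approx(AREA95_IDENTITY, rel=1e-9)

    def test_sqrt_det_scaling(self):
        area = geometry.prediction_ellipse_area(np.diag([4.0, 1.0]), 0.95)
        assert area == pytest.approx(2.0 * AREA95_IDENTITY, rel=1e-9)

    def test_area_vanishes_as_p_to_zero(self):
        assert geometry.prediction_ellipse_area(np.eye(2), 1e-12) < 1e-8

    def test_non_positive_definite_rejected(self):
        with pytest.raises(geometry.DegenerateGeometryError):
            geometry.prediction_ellipse_area(np.array([[1.0, 2.0], [2.0, 1.0]]), 0.95)

    @given(c=st.floats(0.01, 100.0), seed=st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_covariance_scale(self, c, seed):
        cov = _random_spd(np.random.default_rng(seed))
        a1 = geometry.prediction_ellipse_area(cov, 0.95)
        a2 = geometry.prediction_ellipse_area(cov * c, 0.95)
        assert a2 == pytest.approx(c * a1, rel=1e-9)


class TestSmallSampleCorrection:
    @pytest.mark.parametrize("n, factor", [(4, 1.5), (3, 2.0), (1000, 999 / 998)])
    def test_correction_factor(self, rng, n, factor):
        pts = rng.normal(size=(n, 2))
        e = geometry.fit_ellipse("x", pts)
        assert e.area_ell95c / e.area_ell95 == pytest.approx(factor, rel=1e-12)
        # boundary polygon carries the same correction as the area
        assert e.boundary.area / e.area_ell95 == pytest.approx(factor, rel=1e-4)

    def test_correction_undefined_below_three(self, rng):
        pts = rng.normal(size=(3, 2))
        e = geometry.fit_ellipse("x", pts)
        bad = geometry.NicheEllipse(
            owner_id="y", mean=e.mean, covariance=e.covariance, n=2,
            p_level=0.95, area_ell95=1.0, area_ell95c=1.0, boundary=e.boundary,
        )
        with pytest.raises(geometry.InsufficientDataError):
            geometry.small_sample_correct(bad)


class TestEllipseBoundary:
    def test_vertices_satisfy_quadratic_form(self, rng):
        cov = _random_spd(rng)
        mean = np.array([-18.0, 11.0])
        poly = geometry.ellipse_boundary(mean, cov, 0.95, 64)
        inv = np.linalg.inv(cov)
        for x, y in poly.exterior.coords[:-1]:
            d = np.array([x, y]) - mean
            assert d @ inv @ d == pytest.approx(Q95, rel=1e-9)

    def test_polygon_area_converges_to_analytic(self):
        analytic = AREA95_IDENTITY
        poly = geometry.ellipse_boundary([0, 0], np.eye(2), 0.95, 4096)
        assert abs(poly.area - analytic) / analytic < 1e-4  # 0.01%
        errs = []
        for n in (64, 128, 256):
            p = geometry.ellipse_boundary([0, 0], np.eye(2), 0.95, n)
            errs.append(abs(p.area - analytic) / analytic)
        # quadratic convergence: quadrupling vertices ≈ 16x smaller error
        assert errs[2] < errs[0] / 10

    def test_rotation_leaves_area_unchanged(self, rng):
        cov = _random_spd(rng)
        theta = np.pi / 6
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        a1 = geometry.ellipse_boundary([0, 0], cov, 0.95, 1024).area
        a2 = geometry.ellipse_boundary([0, 0], rot @ cov @ rot.T, 0.95, 1024).area
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            geometry.ellipse_boundary([0, 0], np.eye(2), 0.95, 8)


class TestUnionArea:
    def test_single_polygon_is_identity(self):
        poly = geometry.ellipse_boundary([0, 0], np.eye(2), 0.95, 256)
        _, area = geometry.union_area([poly])
        assert area == pytest.approx(poly.area, rel=1e-12)

    def test_disjoint_congruent_polygons_add(self):
        p1 = geometry.ellipse_boundary([0, 0], np.eye(2), 0.95, 256)
        p2 = geometry.ellipse_boundary([100, 0], np.eye(2), 0.95, 256)
        _, area = geometry.union_area([p1, p2])
        assert area == pytest.approx(2 * p1.area, rel=1e-9)

    def test_coincident_polygons_idempotent(self):
        p1 = geometry.ellipse_boundary([0, 0], np.eye(2), 0.95, 256)
        p2 = geometry.ellipse_boundary([0, 0], np.eye(2), 0.95, 256)
        _, area = geometry.union_area([p1, p2])
        assert area == pytest.approx(p1.area, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            geometry.union_area([])

    def test_union_monotone_under_additions(self, rng):
        polys = [
            geometry.ellipse_boundary(rng.normal(size=2), _random_spd(rng), 0.95, 128)
            for _ in range(6)
        ]
        prev = 0.0
        for i in range(1, 7):
            _, area = geometry.union_area(polys[:i])
            assert area >= prev - 1e-12
            prev = area

    def test_union_against_monte_carlo_oracle(self, rng):
        """Exact polygon union vs point-in-any-ellipse Monte Carlo."""
        means = rng.normal(scale=1.5, size=(5, 2))
        covs = [_random_spd(rng) for _ in range(5)]
        polys = [
            geometry.ellipse_boundary(m, c, 0.95, 512) for m, c in zip(means, covs)
        ]
        _, exact = geometry.union_area(polys)

        xs = np.concatenate([np.asarray(p.exterior.coords)[:, 0] for p in polys])
        ys = np.concatenate([np.asarray(p.exterior.coords)[:, 1] for p in polys])
        lo = np.array([xs.min(), ys.min()])
        hi = np.array([xs.max(), ys.max()])
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        inside = np.zeros(len(pts), dtype=bool)
        for m, c in zip(means, covs):
            d = pts - m
            inv = np.linalg.inv(c)
            inside |= np.einsum("ij,jk,ik->i", d, inv, d) <= Q95
        mc = inside.mean() * np.prod(hi - lo)
        assert exact == pytest.approx(mc, rel=0.005)


class TestRINI:
    def _ellipse_at(self, x, owner="a"):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]]) + [x, 0]
        return geometry.fit_ellipse(owner, pts)

    def test_single_member_group_is_one(self):
        niche = geometry.build_group_niche("G", [self._ellipse_at(0)])
        (rec,) = geometry.compute_rini(niche)
        assert rec.rini == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_equal_members_get_half(self):
        e1, e2 = self._ellipse_at(0, "a"), self._ellipse_at(100, "b")
        niche = geometry.build_group_niche("G", [e1, e2])
        for rec in geometry.compute_rini(niche):
            assert rec.rini == pytest.approx(0.5, rel=1e-6)

    def test_coincident_members_get_one(self):
        e1, e2 = self._ellipse_at(0, "a"), self._ellipse_at(0, "b")
        niche = geometry.build_group_niche("G", [e1, e2])
        for rec in geometry.compute_rini(niche):
            assert rec.rini == pytest.approx(1.0, abs=1e-9)

    def test_sqrt_field_consistent(self, rng):
        ellipses = [
            geometry.fit_ellipse(f"i{k}", rng.normal(size=(5, 2)) + rng.normal(size=2))
            for k in range(4)
        ]
        for rec in geometry.compute_rini(geometry.build_group_niche("G", ellipses)):
            assert rec.sqrt_rini == pytest.approx(math.sqrt(rec.rini))

    def test_rini_bounds_and_conservation_on_random_groups(self, rng):
        """All RINI in (0, 1]; ΣRINI ≥ 1 (union is at most the sum of parts)."""
        for _ in range(100):
            k = int(rng.integers(1, 8))
            ellipses = []
            for j in range(k):
                pts = rng.normal(size=(int(rng.integers(4, 8)), 2)) * rng.uniform(
                    0.5, 2.0
                ) + rng.normal(scale=2.0, size=2)
                ellipses.append(geometry.fit_ellipse(f"i{j}", pts))
            niche = geometry.build_group_niche("G", ellipses)
            records = geometry.compute_rini(niche)
            total = sum(r.rini for r in records)
            assert all(0.0 < r.rini <= 1.0 for r in records)
            assert total >= 1.0 - 1e-9


class TestGeoJSONExport:
    def test_group_export_carries_members_and_union(self, rng):
        ellipses = [
            geometry.fit_ellipse(f"i{k}", rng.normal(size=(5, 2)) + [3 * k, 0])
            for k in range(3)
        ]
        group = geometry.build_group_niche("G", ellipses)
        collection = geometry.group_geojson(group)
        assert collection["type"] == "FeatureCollection"
        assert len(collection["features"]) == 4  # 3 members + union outline
        member = collection["features"][0]
        assert member["geometry"]["type"] == "Polygon"
        assert member["properties"]["owner_id"] == "i0"
        ring = member["geometry"]["coordinates"][0]
        assert ring[0] == ring[-1]  # closed ring
        union = collection["features"][-1]
        assert union["properties"]["union_area"] == pytest.approx(group.union_area)
        import json

        json.dumps(collection)  # must be serialisable as-is


class TestPooledGroupEllipse:
    def test_single_individual_group_equals_individual(self, rng):
        pts = rng.normal(size=(6, 2))
        ind = geometry.fit_ellipse("i", pts)
        pooled = geometry.pooled_group_ellipse("G", pts)
        assert pooled.area_ell95c == pytest.approx(ind.area_ell95c, rel=1e-12)

    def test_pooled_n_drives_correction(self, rng):
        pts = rng.normal(size=(40, 2))
        pooled = geometry.pooled_group_ellipse("G", pts)
        assert pooled.n == 40
        assert pooled.area_ell95c / pooled.area_ell95 == pytest.approx(39 / 38)

    def test_duplicated_points_shrink_correction(self, rng):
        """Doubling every point: covariance by the hand (n−1) formula, smaller correction."""
        pts = rng.normal(size=(5, 2))
        doubled = np.vstack([pts, pts])
        _, cov_hand = geometry.fit_mean_covariance(doubled)
        dev = doubled - doubled.mean(axis=0)
        np.testing.assert_allclose(cov_hand, dev.T @ dev / (len(doubled) - 1))
        e1 = geometry.pooled_group_ellipse("G", pts)
        e2 = geometry.pooled_group_ellipse("G", doubled)
        assert e2.correction < e1.correction
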