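"""Bivariate isotopic niche geometry.

An individual's isotopic niche is summarised by the 95% ellipse of the
bivariate normal fitted to its (δ13C, δ15N) samples.  For a fitted
covariance Σ̂ the p-level ellipse is the set

    (x − μ̂)ᵀ Σ̂⁻¹ (x − μ̂) = q(p),      q(p) = chi-square(2 df) quantile,

whose area is π · q(p) · √det(Σ̂) (written ``ell95`` at p = 0.95).  Small
samples underestimate the ellipse, so the covariance is rescaled by
(n − 1)/(n − 2) before use ("ell95c"), which multiplies the area by the
same factor and keeps boundary and area mutually consistent.

A social group's niche is the region covered when all member ellipses are
overlaid — the union of the ellipse interiors, computed here by exact
polygon boolean operations on finely discretised boundaries.  The relative
individual niche index (RINI) expresses each member's corrected ellipse
area as a proportion of that union area: values near 1 mean the individual
ranges over most of its group's niche; small values mean a specialised
individual using a narrow slice of it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "NicheEllipse",
    "GroupNiche",
    "RINIRecord",
    "InsufficientDataError",
    "DegenerateGeometryError",
    "fit_mean_covariance",
    "prediction_ellipse_area",
    "small_sample_correct",
    "ellipse_boundary",
    "union_area",
    "fit_ellipse",
    "build_group_niche",
    "compute_rini",
    "pooled_group_ellipse",
]

DEFAULT_P_LEVEL = 0.95
DEFAULT_N_VERTICES = 512

# Relative determinant threshold below which a covariance is treated as
# numerically singular (points collinear to tolerance).
_DEGENERACY_REL_DET = 1e-12


class InsufficientDataError(ValueError):
    """Too few samples to estimate the requested quantity."""


class DegenerateGeometryError(ValueError):
    """Covariance is (numerically) singular; no ellipse exists."""


@dataclass(frozen=True)
class NicheEllipse:
    """A fitted p-level niche ellipse in (δ13C, δ15N) space.

    ``area_ell95`` is the uncorrected ellipse area at ``p_level``;
    ``area_ell95c`` carries the (n−1)/(n−2) small-sample correction.
    ``boundary`` is the polygonised *corrected* boundary, so that unions of
    these polygons and the corrected areas refer to the same shapes.
    """

    owner_id: str
    mean: np.ndarray
    covariance: np.ndarray
    n: int
    p_level: float
    area_ell95: float
    area_ell95c: float
    boundary: Polygon

    @property
    def correction(self) -> float:
        return (self.n - 1) / (self.n - 2)


@dataclass(frozen=True)
class GroupNiche:
    """Member ellipses of one social group and the union of their interiors."""

    group_id: str
    member_ellipses: tuple[NicheEllipse, ...]
    union_polygon: object  # Polygon or MultiPolygon
    union_area: float
    pooled_ellipse: NicheEllipse | None = None


@dataclass(frozen=True)
class RINIRecord:
    """One individual's relative niche index with its model covariates."""

    individual_id: str
    group_id: str
    rini: float
    sqrt_rini: float
    age_years: float | None = None
    sex: str | None = None
    group_size: float | None = None
    group_size_class: str | None = None
    proportion_sampled: float | None = None


def _check_covariance(covariance: np.ndarray) -> np.ndarray:
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError(f"covariance must be 2x2, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12):
        raise ValueError("covariance must be symmetric")
    det = float(np.linalg.det(cov))
    scale = (np.trace(cov) / 2.0) ** 2
    if det <= _DEGENERACY_REL_DET * scale or scale == 0.0:
        raise DegenerateGeometryError(
            f"covariance is numerically singular (det={det:.3e})"
        )
    return cov


def fit_mean_covariance(points: Iterable[Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and unbiased (n−1) covariance of 2-d points.

    Raises :class:`InsufficientDataError` below three points and
    :class:`DegenerateGeometryError` when the points are collinear within
    tolerance (the fitted ellipse would have zero width).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of points, got shape {pts.shape}")
    if pts.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 points to fit a covariance, got {pts.shape[0]}"
        )
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    return mean, _check_covariance(cov)


def chi2_quantile(p_level: float) -> float:
    """Chi-square (2 df) quantile that scales the ellipse to probability p."""
    if not 0.0 < p_level < 1.0:
        raise ValueError(f"p_level must be in (0, 1), got {p_level}")
    return float(stats.chi2.ppf(p_level, df=2))


def prediction_ellipse_area(covariance: np.ndarray, p_level: float = DEFAULT_P_LEVEL) -> float:
    """Area of the p-level ellipse: π · q(p) · √det(Σ)."""
    cov = _check_covariance(covariance)
    return float(np.pi * chi2_quantile(p_level) * np.sqrt(np.linalg.det(cov)))


def small_sample_correct(ellipse: NicheEllipse) -> NicheEllipse:
    """Rescale covariance (hence area and boundary) by (n−1)/(n−2)."""
    if ellipse.n < 3:
        raise InsufficientDataError("small-sample correction undefined for n < 3")
    factor = (ellipse.n - 1) / (ellipse.n - 2)
    cov_c = ellipse.covariance * factor
    boundary = ellipse_boundary(ellipse.mean, cov_c, ellipse.p_level, _n_vertices_of(ellipse))
    return replace(
        ellipse,
        area_ell95c=ellipse.area_ell95 * factor,
        boundary=boundary,
    )


def _n_vertices_of(ellipse: NicheEllipse) -> int:
    return max(len(ellipse.boundary.exterior.coords) - 1, 16)


def ellipse_boundary(
    mean: Sequence[float],
    covariance: np.ndarray,
    p_level: float = DEFAULT_P_LEVEL,
    n_vertices: int = DEFAULT_N_VERTICES,
) -> Polygon:
    """Polygonise the p-level ellipse boundary.

    Vertices are the Cholesky image of ``n_vertices`` uniformly spaced
    points on the circle of radius √q(p); every vertex satisfies the
    defining quadratic form exactly (to floating point), and the polygon
    area converges to the analytic area as O(1/n_vertices²).
    """
    if n_vertices < 16:
        raise ValueError(f"n_vertices must be >= 16, got {n_vertices}")
    cov = _check_covariance(covariance)
    mu = np.asarray(mean, dtype=float)
    radius = np.sqrt(chi2_quantile(p_level))
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)]) * radius
    chol = np.linalg.cholesky(cov)
    verts = mu + circle @ chol.T
    return Polygon(verts)


def union_area(polygons: Sequence[Polygon]) -> tuple[object, float]:
    """Set-union of ellipse polygons and its area (multi-part allowed)."""
    polys = list(polygons)
    if not polys:
        raise ValueError("union of an empty polygon collection is undefined")
    union = unary_union(polys)
    return union, float(union.area)


def fit_ellipse(
    owner_id: str,
    points: Iterable[Sequence[float]],
    p_level: float = DEFAULT_P_LEVEL,
    n_vertices: int = DEFAULT_N_VERTICES,
) -> NicheEllipse:
    """Fit the corrected niche ellipse to one individual's samples.

    The returned boundary polygon is that of the *corrected* covariance
    Σ̂ · (n−1)/(n−2), so RINI numerators and the group union are computed
    from the same geometry.
    """
    pts = np.asarray(list(points), dtype=float)
    mean, cov = fit_mean_covariance(pts)
    n = pts.shape[0]
    area = prediction_ellipse_area(cov, p_level)
    factor = (n - 1) / (n - 2)
    boundary = ellipse_boundary(mean, cov * factor, p_level, n_vertices)
    return NicheEllipse(
        owner_id=owner_id,
        mean=mean,
        covariance=cov,
        n=n,
        p_level=p_level,
        area_ell95=area,
        area_ell95c=area * factor,
        boundary=boundary,
    )


def build_group_niche(
    group_id: str,
    ellipses: Sequence[NicheEllipse],
    pooled: NicheEllipse | None = None,
) -> GroupNiche:
    """Overlay member ellipses into the group niche (union of interiors)."""
    if not ellipses:
        raise ValueError(f"group {group_id!r} has no member ellipses")
    union, area = union_area([e.boundary for e in ellipses])
    return GroupNiche(
        group_id=group_id,
        member_ellipses=tuple(ellipses),
        union_polygon=union,
        union_area=area,
        pooled_ellipse=pooled,
    )


def compute_rini(group: GroupNiche) -> list[RINIRecord]:
    """Each member's corrected ellipse area as a proportion of the group union.

    Numerator and denominator both use the polygonised corrected shapes, so
    the ratio is internally consistent at any vertex count: a single-member
    group yields RINI exactly 1, coincident members all get 1, and disjoint
    members' values sum to exactly 1.  Tiny floating-point excursions above
    1 (a member polygon is a subset of the union by construction) are
    clamped.
    """
    if not group.member_ellipses:
        raise ValueError("cannot compute RINI for an empty group")
    records = []
    for e in group.member_ellipses:
        rini = min(e.boundary.area / group.union_area, 1.0)
        records.append(
            RINIRecord(
                individual_id=e.owner_id,
                group_id=group.group_id,
                rini=rini,
                sqrt_rini=float(np.sqrt(rini)),
            )
        )
    return records


def _polygon_coordinates(shape) -> list:
    if shape.geom_type == "Polygon":
        return [[list(map(float, xy)) for xy in shape.exterior.coords]]
    # MultiPolygon: one ring list per part
    return [
        [list(map(float, xy)) for xy in part.exterior.coords] for part in shape.geoms
    ]


def ellipse_geojson(ellipse: NicheEllipse) -> dict:
    """GeoJSON-style feature for one corrected niche ellipse.

    Coordinates live in (δ13C, δ15N) space, not geographic space.
    """
    return {
        "type": "Feature",
        "geometry": {
            "type": "Polygon",
            "coordinates": _polygon_coordinates(ellipse.boundary),
        },
        "properties": {
            "owner_id": ellipse.owner_id,
            "n": ellipse.n,
            "p_level": ellipse.p_level,
            "area_ell95": ellipse.area_ell95,
            "area_ell95c": ellipse.area_ell95c,
        },
    }


def group_geojson(group: GroupNiche) -> dict:
    """Feature collection: member ellipses plus the union outline."""
    union_type = (
        "Polygon" if group.union_polygon.geom_type == "Polygon" else "MultiPolygon"
    )
    coords = _polygon_coordinates(group.union_polygon)
    features = [ellipse_geojson(e) for e in group.member_ellipses]
    features.append(
        {
            "type": "Feature",
            "geometry": {
                "type": union_type,
                "coordinates": coords if union_type == "Polygon" else [[c] for c in coords],
            },
            "properties": {"group_id": group.group_id, "union_area": group.union_area},
        }
    )
    return {"type": "FeatureCollection", "features": features}


def pooled_group_ellipse(
    group_id: str,
    points: Iterable[Sequence[float]],
    p_level: float = DEFAULT_P_LEVEL,
    n_vertices: int = DEFAULT_N_VERTICES,
) -> NicheEllipse:
    """Corrected ellipse over all samples pooled across a group's members.

    The correction uses the pooled sample count, so a well-sampled group's
    correction factor approaches 1 even when its members are each sparsely
    sampled.
    """
    return fit_ellipse(group_id, points, p_level=p_level, n_vertices=n_vertices)
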