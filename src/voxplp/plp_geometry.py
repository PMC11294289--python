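"""Shape descriptors of polygonal language profiles (PLPs).

A PLP is the closed polygon obtained by plotting the four verbal-operant
totals on the axes of a radar chart and joining adjacent points.  The
canonical axis layout places echoic on +x, mand on +y, sequelic on -x and
tact on -y, so each quadrant between adjacent axes represents convergent
multiple control of those two operants (Q1 echoic&mand, Q2 mand&sequelic,
Q3 sequelic&tact, Q4 tact&echoic).

Four descriptors summarize a profile:

* area ``A`` — the total size of the profile (axis-units^2);
* centroid ``(x_bar, y_bar)`` — its geometric center, the repertoire's
  locus of control (a perfectly balanced repertoire has centroid (0, 0));
* centroidal distance ``R = sqrt(x_bar^2 + y_bar^2)`` — imbalance;
* first moment of area ``Q = A * (C - R)`` — size weighted by balance,
  where ``C`` is the radius of the circle circumscribing the property
  space (the largest attainable profile).

All descriptors are computed from an origin-anchored triangle decomposition
of the polygon: one triangle per pair of adjacent axes, with the chart
origin as the shared vertex.  For non-negative axis values on evenly spaced
axes this decomposition is exact — triangle areas sum to the polygon area
and the area-weighted triangle centroids average to the true polygon
centroid (it coincides with the shoelace formula on the vertices).

This module is pure computation: it consumes axis values and a radar
configuration and emits descriptors; file I/O lives in :mod:`voxplp.vox_data`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .vox_data import OPERANTS, AxisValues

#: Canonical cyclic axis order: echoic on +x, then counterclockwise.
CANONICAL_AXIS_ORDER: tuple[str, ...] = ("echoic", "mand", "sequelic", "tact")

_SNAP = 1e-12  # zero out cos/sin residue on quarter-turn axes


@dataclass(frozen=True)
class RadarConfig:
    """Geometry of the radar chart a profile is plotted on.

    Parameters
    ----------
    property_radius
        Radius ``C`` of the circle circumscribing the property space, i.e.
        the maximum attainable value on any axis.  It is instrument-specific
        (e.g. number of response forms times rounds), so there is no
        default: operations that need it (the first moment ``Q``) raise if
        it is unset.
    axis_order
        Cyclic order of operant labels around the chart, starting on the +x
        axis and proceeding counterclockwise.  Must be a permutation of the
        four operants.
    ordering_mode
        ``"canonical"`` keeps the semantic axis positions; ``"maximize"``
        re-orders axes to attain the maximal total area before computing
        descriptors.
    radius_policy
        What to do when an axis value exceeds ``property_radius``:
        ``"warn"`` (default) or ``"error"``.
    """

    property_radius: float | None = None
    axis_order: tuple[str, ...] = CANONICAL_AXIS_ORDER
    ordering_mode: str = "canonical"
    radius_policy: str = "warn"

    def __post_init__(self) -> None:
        if sorted(self.axis_order) != sorted(OPERANTS):
            raise ValueError(
                f"axis_order must be a permutation of {OPERANTS}, got {self.axis_order}"
            )
        if self.ordering_mode not in ("canonical", "maximize"):
            raise ValueError(f"unknown ordering_mode {self.ordering_mode!r}")
        if self.radius_policy not in ("warn", "error"):
            raise ValueError(f"unknown radius_policy {self.radius_policy!r}")
        if self.property_radius is not None and self.property_radius <= 0:
            raise ValueError("property_radius must be positive")

    @property
    def n_axes(self) -> int:
        return len(self.axis_order)

    def check_radius(self, values: AxisValues) -> None:
        """Enforce C >= max axis value according to ``radius_policy``."""
        if self.property_radius is None:
            return
        vmax = max(values.as_tuple())
        if vmax > self.property_radius:
            msg = (
                f"axis value {vmax} exceeds property_radius "
                f"C={self.property_radius}; the profile leaves the property space"
            )
            if self.radius_policy == "error":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)


def axis_unit_vectors(n_axes: int) -> list[tuple[float, float]]:
    """Unit vectors of ``n_axes`` evenly spaced axes, axis 0 on +x, CCW."""
    units = []
    for i in range(n_axes):
        theta = 2.0 * math.pi * i / n_axes
        x, y = math.cos(theta), math.sin(theta)
        units.append((0.0 if abs(x) < _SNAP else x, 0.0 if abs(y) < _SNAP else y))
    return units


@dataclass(frozen=True)
class PolygonalLanguageProfile:
    """Ordered Cartesian vertices of one radar profile plus its config."""

    axis_values: AxisValues
    config: RadarConfig
    vertices: tuple[tuple[float, float], ...]

    @property
    def values_in_order(self) -> tuple[float, ...]:
        return self.axis_values.as_tuple(self.config.axis_order)


def build_profile(values: AxisValues, config: RadarConfig) -> PolygonalLanguageProfile:
    """Place each operant total on its axis and close the polygon.

    Under the canonical order the vertices are ``(echoic, 0)``,
    ``(0, mand)``, ``(-sequelic, 0)``, ``(0, -tact)``.  All-zero values give
    a degenerate profile with every vertex at the origin.
    """
    config.check_radius(values)
    ordered = values.as_tuple(config.axis_order)
    units = axis_unit_vectors(config.n_axes)
    vertices = tuple((v * ux, v * uy) for v, (ux, uy) in zip(ordered, units))
    return PolygonalLanguageProfile(axis_values=values, config=config, vertices=vertices)


def _adjacent_products(ordered: Sequence[float]) -> float:
    n = len(ordered)
    return sum(ordered[i] * ordered[(i + 1) % n] for i in range(n))


def polygon_area(plp: PolygonalLanguageProfile) -> float:
    """Area ``A`` of the profile.

    Adjacent axis values ``v_i, v_{i+1}`` and the origin form a triangle of
    area ``(1/2) v_i v_{i+1} sin(2*pi/n)``; summing cyclically gives

        ``A = (1/2) sin(2*pi/n) * sum_i v_i v_{i+1}``.

    For the 4-axis chart ``sin(2*pi/4) = 1`` and this is the quadrant
    base-times-height sum ``(1/2) sum |x_i||y_{i+1}|``; it equals the
    shoelace area of the vertices.
    """
    n = plp.config.n_axes
    return 0.5 * math.sin(2.0 * math.pi / n) * _adjacent_products(plp.values_in_order)


@dataclass(frozen=True)
class TriangleDecomposition:
    """Origin-anchored triangles of a profile: one per adjacent-axis pair."""

    areas: tuple[float, ...]
    centroids: tuple[tuple[float, float], ...]

    @property
    def total_area(self) -> float:
        return sum(self.areas)


def triangle_decomposition(plp: PolygonalLanguageProfile) -> TriangleDecomposition:
    """Split the profile into triangles (origin, vertex_i, vertex_{i+1}).

    Each triangle's centroid is the mean of its three vertices with signed
    coordinates; its area is half the cross product of the two vertex
    vectors (non-negative for counterclockwise axis order).
    """
    verts = plp.vertices
    n = len(verts)
    areas: list[float] = []
    centroids: list[tuple[float, float]] = []
    for i in range(n):
        (x1, y1), (x2, y2) = verts[i], verts[(i + 1) % n]
        areas.append(0.5 * abs(x1 * y2 - x2 * y1))
        centroids.append(((x1 + x2) / 3.0, (y1 + y2) / 3.0))
    return TriangleDecomposition(areas=tuple(areas), centroids=tuple(centroids))


def quadrant_convergence(
    plp: PolygonalLanguageProfile,
) -> tuple[tuple[float, ...], tuple[float, ...] | None]:
    """Per-quadrant areas and shares of the profile.

    Quadrant ``i`` (between axes ``i`` and ``i+1``) holds the right triangle
    of area ``(1/2) v_i v_{i+1}`` (4-axis chart); its share of the total area
    measures the relative strength of convergent multiple control by that
    pair of operants.  Shares are ``None`` for a degenerate (zero-area)
    profile.
    """
    decomp = triangle_decomposition(plp)
    total = decomp.total_area
    if total > 0.0:
        shares: tuple[float, ...] | None = tuple(a / total for a in decomp.areas)
    else:
        shares = None
    return decomp.areas, shares


def centroid(plp: PolygonalLanguageProfile) -> tuple[float, float] | None:
    """Area-weighted mean of the triangle centroids; the profile's centroid.

    Returns ``None`` for a degenerate zero-area profile, whose centroid is
    undefined.
    """
    decomp = triangle_decomposition(plp)
    total = decomp.total_area
    if total <= 0.0:
        return None
    x_bar = sum(a * cx for a, (cx, _) in zip(decomp.areas, decomp.centroids)) / total
    y_bar = sum(a * cy for a, (_, cy) in zip(decomp.areas, decomp.centroids)) / total
    return (x_bar, y_bar)


def centroidal_distance(center: tuple[float, float] | None) -> float | None:
    """Euclidean distance ``R`` from the chart origin to the centroid."""
    if center is None:
        return None
    return math.hypot(center[0], center[1])


def first_moment(
    area: float,
    centroidal_dist: float | None,
    config: RadarConfig,
    permissive: bool = False,
) -> float:
    """First moment of area ``Q = A * (C - R)``.

    ``C`` is ``config.property_radius`` and must be set.  A zero-area
    profile has ``Q = 0`` regardless of the (undefined) centroid.  ``C < R``
    means the centroid lies outside the declared property space; that is
    rejected unless ``permissive=True``, in which case a negative ``Q`` is
    returned with a warning.
    """
    if config.property_radius is None:
        raise ValueError(
            "first moment of area requires the property radius C; "
            "set RadarConfig.property_radius to the instrument's maximum axis value"
        )
    if area == 0.0:
        return 0.0
    if centroidal_dist is None:
        raise ValueError("centroidal distance undefined for a nonzero-area profile")
    if centroidal_dist > config.property_radius:
        msg = (
            f"centroidal distance R={centroidal_dist} exceeds property radius "
            f"C={config.property_radius}"
        )
        if not permissive:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return area * (config.property_radius - centroidal_dist)


def _cyclic_orderings(n: int) -> list[tuple[int, ...]]:
    """Distinct cyclic orderings of n items up to rotation and reflection.

    Normal form: index 0 first, and the second element smaller than the
    last (fixing the reflection).  There are (n-1)!/2 of them for n >= 3.
    """
    orderings = []
    for perm in itertools.permutations(range(1, n)):
        if perm[0] < perm[-1]:
            orderings.append((0, *perm))
    return orderings


def maximize_area_ordering(
    values: AxisValues | Sequence[float],
    axis_order: Sequence[str] | None = None,
) -> tuple[tuple[str, ...] | tuple[int, ...], float]:
    """Axis ordering attaining the maximal total area ``A-tilde``.

    Enumerates all ``(n-1)!/2`` cyclic orderings up to rotation and
    reflection (brute force; intended for n <= 10) and returns one that
    maximizes the adjacent-product sum, together with the maximal area.
    Ties break deterministically toward the ordering closest to canonical
    in the normal-form lexicographic sense, so the canonical order is
    returned whenever it attains the maximum.
    """
    if isinstance(values, AxisValues):
        labels: tuple[str, ...] | None = tuple(
            axis_order if axis_order is not None else CANONICAL_AXIS_ORDER
        )
        vals: tuple[float, ...] = values.as_tuple(labels)
    else:
        labels = tuple(axis_order) if axis_order is not None else None
        vals = tuple(float(v) for v in values)
    n = len(vals)
    if n > 10:
        raise ValueError(f"ordering search is brute-force; n={n} exceeds 10 axes")
    if n < 3:
        raise ValueError("a radar chart needs at least 3 axes")

    best: tuple[int, ...] | None = None
    best_sum = -math.inf
    for ordering in _cyclic_orderings(n):  # normal forms in lexicographic order
        s = _adjacent_products([vals[i] for i in ordering])
        if s > best_sum + 1e-12:
            best, best_sum = ordering, s
    assert best is not None
    a_tilde = 0.5 * math.sin(2.0 * math.pi / n) * best_sum
    if labels is not None:
        return tuple(labels[i] for i in best), a_tilde
    return best, a_tilde


@dataclass(frozen=True)
class ShapeDescriptors:
    """The full descriptor set of one profile.

    ``centroid`` and ``centroidal_distance`` are ``None`` for a degenerate
    zero-area profile (``first_moment`` is then 0).  ``first_moment`` is
    ``None`` when no property radius was configured.
    """

    area: float
    area_max: float | None = None
    max_ordering: tuple[str, ...] | None = None
    centroid: tuple[float, float] | None = None
    centroidal_distance: float | None = None
    first_moment: float | None = None
    quadrant_areas: tuple[float, ...] = ()
    quadrant_shares: tuple[float, ...] | None = None
    axis_values: AxisValues | None = None
    axis_order: tuple[str, ...] = CANONICAL_AXIS_ORDER
    property_radius: float | None = None

    @property
    def degenerate(self) -> bool:
        return self.area == 0.0

    @classmethod
    def from_reported(
        cls,
        area: float,
        centroidal_distance: float | None,
        property_radius: float,
        first_moment: float | None = None,
        centroid: tuple[float, float] | None = None,
        axis_values: AxisValues | None = None,
        axis_order: tuple[str, ...] = CANONICAL_AXIS_ORDER,
    ) -> "ShapeDescriptors":
        """Wrap descriptors transcribed from a report (axis values unknown).

        ``first_moment`` defaults to ``A * (C - R)`` recomputed from the
        reported values when not given.
        """
        if first_moment is None and centroidal_distance is not None:
            first_moment = area * (property_radius - centroidal_distance)
        return cls(
            area=area,
            centroid=centroid,
            centroidal_distance=centroidal_distance,
            first_moment=first_moment,
            axis_values=axis_values,
            axis_order=axis_order,
            property_radius=property_radius,
        )


def describe(values: AxisValues, config: RadarConfig) -> ShapeDescriptors:
    """Compute every shape descriptor of one profile.

    With ``ordering_mode="maximize"`` the axis order achieving the maximal
    total area is applied before anything else; with ``"canonical"`` the
    semantic axis positions are kept (the maximal area is still reported as
    ``area_max``).  ``first_moment`` requires ``config.property_radius``.
    """
    max_ordering, a_tilde = maximize_area_ordering(values, config.axis_order)
    effective = config
    if config.ordering_mode == "maximize":
        effective = replace(config, axis_order=tuple(max_ordering))
    plp = build_profile(values, effective)
    area = polygon_area(plp)
    q_areas, q_shares = quadrant_convergence(plp)
    center = centroid(plp)
    r = centroidal_distance(center)
    q = None
    if config.property_radius is not None:
        q = first_moment(area, r, effective)
    return ShapeDescriptors(
        area=area,
        area_max=a_tilde,
        max_ordering=tuple(max_ordering),
        centroid=center,
        centroidal_distance=r,
        first_moment=q,
        quadrant_areas=q_areas,
        quadrant_shares=q_shares,
        axis_values=values,
        axis_order=effective.axis_order,
        property_radius=config.property_radius,
    )
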