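"""Circular geometry of the globe.

The rim of a unit circle is divided into one contiguous arc per domain,
separated by fixed angular gaps. Angles are measured in degrees, clockwise,
with 0° at 12 o'clock. Each domain's arc length is proportional to its
variable count (each variable needs one rim slot); variables sit at the
midpoints of equal slots within their domain's arc, and every ribbon is a
single cubic Bézier whose control points are pulled toward the circle
center, giving the classic chord-diagram "stretch across the globe" look.

All computation is done in normalized unit-circle coordinates; rendering
applies the only scaling. The pipeline contains no randomness and all
tie-breaks are first-appearance order, so identical inputs give identical
layouts bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import BadExplicitOrder, DegenerateRibbon, GapTooLarge
from .model import Domain, GlobeModel

SORT_MODES = ("size", "none", "explicit")

Point = tuple[float, float]


def unit_point(angle_deg: float) -> Point:
    """Point on the unit circle at ``angle_deg`` (0° = 12 o'clock, clockwise).

    Coordinates are mathematical (y up): 0° -> (0, 1), 90° -> (1, 0).
    """
    rad = math.radians(angle_deg)
    return (math.sin(rad), math.cos(rad))


@dataclass(frozen=True)
class AngularSpan:
    """A clockwise arc from ``start_deg`` to ``end_deg``.

    ``start_deg`` is normalized to [0, 360); ``end_deg`` may exceed 360 so
    that ``end_deg - start_deg`` is the clockwise extent, always in (0, 360).
    """

    start_deg: float
    end_deg: float

    @property
    def extent_deg(self) -> float:
        return self.end_deg - self.start_deg

    @property
    def mid_deg(self) -> float:
        return (self.start_deg + self.end_deg) / 2.0 % 360.0

    def contains(self, angle_deg: float) -> bool:
        """True iff the angle lies strictly inside the arc."""
        rel = (angle_deg - self.start_deg) % 360.0
        return 0.0 < rel < self.extent_deg


@dataclass(frozen=True)
class RibbonGeometry:
    """Cubic Bézier path of one ribbon in unit-circle coordinates."""

    anchor1_deg: float
    anchor2_deg: float
    p0: Point
    c1: Point
    c2: Point
    p3: Point

    def control_points(self) -> tuple[Point, Point, Point, Point]:
        return (self.p0, self.c1, self.c2, self.p3)

    def point_at(self, t: float) -> Point:
        """Evaluate the Bézier at parameter t in [0, 1]."""
        s = 1.0 - t
        px = (s**3 * self.p0[0] + 3 * s**2 * t * self.c1[0]
              + 3 * s * t**2 * self.c2[0] + t**3 * self.p3[0])
        py = (s**3 * self.p0[1] + 3 * s**2 * t * self.c1[1]
              + 3 * s * t**2 * self.c2[1] + t**3 * self.p3[1])
        return (px, py)


@dataclass(frozen=True)
class GlobeLayout:
    """Geometric realization of a model: spans, anchors, ribbon paths."""

    domain_spans: Mapping[str, AngularSpan]  # insertion order = rim order
    variable_anchors: Mapping[tuple[str, str], float]  # (domain, variable) -> deg
    ribbon_geoms: tuple[RibbonGeometry, ...]  # parallel to model.ribbons
    sort_mode: str
    gap_degrees: float
    radius: float = 1.0


def order_domains(
    model: GlobeModel,
    sort_mode: str = "size",
    explicit_order: Sequence[str] | None = None,
) -> list[str]:
    """Rim order of domain labels.

    ``size``: descending by variable count, ties broken by first appearance
    in the input; ``none``: first-appearance order of the source file;
    ``explicit``: the user-chosen permutation (rearranging domains around
    the circumference).
    """
    if sort_mode not in SORT_MODES:
        raise ValueError(f"sort_mode must be one of {SORT_MODES}, got {sort_mode!r}")
    names = list(model.domain_names)
    if sort_mode == "none":
        return names
    if sort_mode == "size":
        # sorted() is stable, so ties keep first-appearance order.
        return sorted(names, key=lambda n: -model.domain(n).size)
    if explicit_order is None:
        raise BadExplicitOrder("sort_mode 'explicit' requires explicit_order")
    explicit = list(explicit_order)
    if sorted(explicit) != sorted(names):
        raise BadExplicitOrder(
            f"explicit order {explicit!r} is not a permutation of the "
            f"present domains {names!r}"
        )
    return explicit


def allocate_angles(
    ordered_domains: Sequence[Domain],
    gap_degrees: float = 2.0,
) -> dict[str, AngularSpan]:
    """Assign each domain a clockwise arc proportional to its variable count.

    The first domain starts at 0° (12 o'clock); one gap follows each domain,
    so extents satisfy ``sum(extents) + n * gap == 360`` exactly (in exact
    arithmetic; floating point keeps it within ~1e-9°).
    """
    n = len(ordered_domains)
    if n == 0:
        raise ValueError("no domains to place")
    if gap_degrees <= 0:
        raise ValueError(f"gap_degrees must be positive, got {gap_degrees}")
    usable = 360.0 - n * gap_degrees
    if usable <= 0:
        raise GapTooLarge(
            f"{n} domains x {gap_degrees}° gaps leave no room on the circle"
        )
    total_vars = sum(d.size for d in ordered_domains)
    spans: dict[str, AngularSpan] = {}
    cursor = 0.0
    for dom in ordered_domains:
        extent = usable * dom.size / total_vars
        spans[dom.name] = AngularSpan(cursor % 360.0, cursor % 360.0 + extent)
        cursor += extent + gap_degrees
    return spans


def anchor_variables(
    span: AngularSpan,
    variables: Sequence[str],
) -> dict[str, float]:
    """Place variables at midpoints of equal slots inside the span, in order."""
    m = len(variables)
    if m == 0:
        raise ValueError("a domain must have at least one variable")
    slot = span.extent_deg / m
    return {
        var: (span.start_deg + slot * (i + 0.5)) % 360.0
        for i, var in enumerate(variables)
    }


def ribbon_path(
    anchor1_deg: float,
    anchor2_deg: float,
    pull: float = 0.8,
) -> RibbonGeometry:
    """Cubic Bézier between two rim anchors.

    Endpoints lie on the unit circle at the anchors; each control point is
    the endpoint's direction scaled by ``1 - pull``, so ``pull = 1`` routes
    every ribbon through the center and ``pull = 0`` leaves the control
    points on the rim. Swapping the anchors yields the same curve traversed
    in the opposite direction.
    """
    if not 0.0 <= pull <= 1.0:
        raise ValueError(f"pull must be in [0, 1], got {pull}")
    if (anchor1_deg - anchor2_deg) % 360.0 == 0.0:
        raise DegenerateRibbon(
            f"both anchors at {anchor1_deg}°; distinct variables always have "
            "distinct anchors"
        )
    p0 = unit_point(anchor1_deg)
    p3 = unit_point(anchor2_deg)
    k = 1.0 - pull
    return RibbonGeometry(
        anchor1_deg=anchor1_deg, anchor2_deg=anchor2_deg,
        p0=p0, c1=(p0[0] * k, p0[1] * k), c2=(p3[0] * k, p3[1] * k), p3=p3,
    )


def compute_layout(
    model: GlobeModel,
    sort_mode: str = "size",
    explicit_order: Sequence[str] | None = None,
    gap_degrees: float = 2.0,
    pull: float = 0.8,
) -> GlobeLayout:
    """Full geometric realization of a model.

    Composes :func:`order_domains`, :func:`allocate_angles`,
    :func:`anchor_variables` and :func:`ribbon_path`; deterministic —
    identical inputs give identical layouts bit-for-bit.
    """
    order = order_domains(model, sort_mode, explicit_order)
    by_name = {d.name: d for d in model.domains}
    spans = allocate_angles([by_name[n] for n in order], gap_degrees)

    anchors: dict[tuple[str, str], float] = {}
    for name in order:
        for var, ang in anchor_variables(spans[name], by_name[name].variables).items():
            anchors[(name, var)] = ang

    geoms = tuple(
        ribbon_path(anchors[(rb.domain1, rb.variable1)],
                    anchors[(rb.domain2, rb.variable2)], pull)
        for rb in model.ribbons
    )
    return GlobeLayout(
        domain_spans=spans, variable_anchors=anchors, ribbon_geoms=geoms,
        sort_mode=sort_mode, gap_degrees=float(gap_degrees),
    )
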