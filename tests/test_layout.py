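"""Circular geometry: ordering, angular allocation, anchors, ribbon curves."""

import itertools
import math

import numpy as np
import pytest

from corrglobe import (
    Domain,
    GlobeModel,
    allocate_angles,
    anchor_variables,
    build_globe,
    compute_layout,
    order_domains,
    ribbon_path,
    unit_point,
)
from corrglobe.errors import BadExplicitOrder, DegenerateRibbon, GapTooLarge
from corrglobe.layout import AngularSpan
from helpers import table_from


def make_model(sizes):
    """A bare model whose domains have the given variable counts, in order."""
    domains = tuple(
        Domain(name, tuple(f"{name}_v{j}" for j in range(n)))
        for name, n in sizes
    )
    return GlobeModel(domains=domains, ribbons=(), threshold=0.0)


class TestOrdering:
    def test_size_mode_sorts_descending(self):
        model = make_model([("A", 5), ("B", 3), ("C", 7)])
        assert order_domains(model, "size") == ["C", "A", "B"]

    def test_none_mode_keeps_first_appearance(self):
        model = make_model([("A", 5), ("B", 3), ("C", 7)])
        assert order_domains(model, "none") == ["A", "B", "C"]

    def test_all_equal_sizes_makes_size_equal_none(self):
        model = make_model([("A", 4), ("B", 4), ("C", 4)])
        assert order_domains(model, "size") == order_domains(model, "none")

    def test_explicit_realizes_any_permutation(self):
        model = make_model([("A", 1), ("B", 2), ("C", 3), ("D", 4)])
        for perm in itertools.permutations("ABCD"):
            assert order_domains(model, "explicit", list(perm)) == list(perm)

    def test_explicit_must_be_a_permutation(self):
        model = make_model([("A", 1), ("B", 2)])
        with pytest.raises(BadExplicitOrder):
            order_domains(model, "explicit", ["A", "Z"])
        with pytest.raises(BadExplicitOrder):
            order_domains(model, "explicit", ["A"])
        with pytest.raises(BadExplicitOrder):
            order_domains(model, "explicit", None)


class TestAllocation:
    def test_two_equal_domains_split_symmetrically(self):
        model = make_model([("A", 3), ("B", 3)])
        spans = allocate_angles(model.domains, gap_degrees=10.0)
        assert spans["A"].extent_deg == pytest.approx((360 - 20) / 2)
        assert spans["B"].extent_deg == pytest.approx((360 - 20) / 2)

    def test_single_domain_takes_whole_circle_minus_gap(self):
        spans = allocate_angles(make_model([("A", 4)]).domains, gap_degrees=7.0)
        assert spans["A"].extent_deg == pytest.approx(353.0)

    def test_extents_proportional_to_variable_count(self):
        model = make_model([("A", 1), ("B", 3)])
        spans = allocate_angles(model.domains, gap_degrees=2.0)
        assert spans["B"].extent_deg == pytest.approx(3 * spans["A"].extent_deg)

    def test_conservation_over_random_size_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 9))
            sizes = [(f"D{i}", int(rng.integers(1, 30))) for i in range(n)]
            gap = float(rng.uniform(0.1, 359.0 / n))
            spans = allocate_angles(make_model(sizes).domains, gap)
            total = sum(s.extent_deg for s in spans.values())
            assert total + n * gap == pytest.approx(360.0, abs=1e-9)

    def test_gap_too_large(self):
        with pytest.raises(GapTooLarge):
            allocate_angles(make_model([("A", 1), ("B", 1)]).domains,
                            gap_degrees=180.0)


class TestAnchors:
    def test_single_variable_sits_at_span_midpoint(self):
        span = AngularSpan(40.0, 100.0)
        assert anchor_variables(span, ["x"]) == {"x": 70.0}

    def test_three_variables_in_thirty_degrees(self):
        anchors = anchor_variables(AngularSpan(0.0, 30.0), ["a", "b", "c"])
        assert list(anchors.values()) == pytest.approx([5.0, 15.0, 25.0])

    def test_anchors_strictly_inside_and_increasing(self, rng):
        for m in (1, 2, 7, 100, 1000):
            start = float(rng.uniform(0, 360))
            extent = float(rng.uniform(1, 300))
            span = AngularSpan(start, start + extent)
            anchors = anchor_variables(span, [f"v{i}" for i in range(m)])
            rel = [(a - span.start_deg) % 360 for a in anchors.values()]
            assert all(span.contains(a) for a in anchors.values())
            assert rel == sorted(rel) and len(set(rel)) == m


class TestRibbonPath:
    def test_full_pull_routes_through_center(self):
        geom = ribbon_path(0.0, 180.0, pull=1.0)
        assert geom.c1 == (0.0, 0.0) and geom.c2 == (0.0, 0.0)
        assert geom.point_at(0.5) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_zero_pull_leaves_controls_on_rim(self):
        geom = ribbon_path(30.0, 120.0, pull=0.0)
        assert geom.c1 == geom.p0 and geom.c2 == geom.p3

    def test_endpoints_on_unit_circle(self, rng):
        for _ in range(100):
            a1, a2 = rng.uniform(0, 360, size=2)
            if (a1 - a2) % 360 == 0:
                continue
            geom = ribbon_path(float(a1), float(a2))
            for p in (geom.p0, geom.p3):
                assert abs(math.hypot(*p) - 1.0) < 1e-12

    def test_swapping_anchors_mirrors_the_curve(self, rng):
        for _ in range(50):
            a1, a2 = float(rng.uniform(0, 360)), float(rng.uniform(0, 360))
            if (a1 - a2) % 360 == 0:
                continue
            fwd = ribbon_path(a1, a2)
            rev = ribbon_path(a2, a1)
            for t in np.linspace(0, 1, 17):
                p, q = fwd.point_at(float(t)), rev.point_at(float(1 - t))
                assert math.dist(p, q) < 1e-9

    def test_identical_anchors_are_degenerate(self):
        with pytest.raises(DegenerateRibbon):
            ribbon_path(45.0, 45.0 + 360.0)


class TestComputeLayout:
    @pytest.fixture
    def model(self):
        table = table_from([
            ("a", "X", "b", "X", 0.9),   # intra-domain
            ("a", "X", "c", "Y", -0.5),
            ("b", "X", "d", "Z", 0.4),
        ])
        return build_globe(table)

    def test_deterministic(self, model):
        assert compute_layout(model) == compute_layout(model)

    def test_intra_domain_ribbon_gets_two_distinct_anchors_in_one_span(self, model):
        layout = compute_layout(model)
        geom = layout.ribbon_geoms[0]
        span = layout.domain_spans["X"]
        assert geom.anchor1_deg != geom.anchor2_deg
        assert span.contains(geom.anchor1_deg) and span.contains(geom.anchor2_deg)

    def test_rim_order_matches_order_domains(self, model):
        layout = compute_layout(model, sort_mode="size")
        assert list(layout.domain_spans) == order_domains(model, "size")
        explicit = ["Z", "X", "Y"]
        layout2 = compute_layout(model, "explicit", explicit)
        assert list(layout2.domain_spans) == explicit

    def test_spans_pairwise_disjoint(self, model):
        layout = compute_layout(model)
        spans = list(layout.domain_spans.values())
        for i, s in enumerate(spans):
            for t in spans[i + 1:]:
                assert not s.contains(t.mid_deg) and not t.contains(s.mid_deg)
                assert not s.contains(t.start_deg % 360.0)

    def test_conservation_survives_domain_exclusion(self):
        table = table_from([
            ("a", "X", "b", "X", 0.9),
            ("c", "Y", "d", "Y", 0.8),
            ("e", "Z", "f", "Z", 0.7),
        ])
        for excluded in ((), ("Y",), ("Y", "Z")):
            model = build_globe(table, excluded=excluded)
            layout = compute_layout(model, gap_degrees=3.0)
            n = len(layout.domain_spans)
            total = sum(s.extent_deg for s in layout.domain_spans.values())
            assert total + n * 3.0 == pytest.approx(360.0, abs=1e-9)

    def test_every_anchor_inside_its_domain_span(self, model):
        layout = compute_layout(model)
        for (dom, _var), ang in layout.variable_anchors.items():
            assert layout.domain_spans[dom].contains(ang)

    def test_angle_convention_clockwise_from_noon(self):
        assert unit_point(0.0) == pytest.approx((0.0, 1.0))
        assert unit_point(90.0) == pytest.approx((1.0, 0.0))
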