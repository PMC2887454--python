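"""Morphology structure, metrics and recompartmentalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nml1 import morphology as m
from nml1.fixtures import ball_and_stick_morphology, sphere_morphology


def straight_cable_cell(radii, seg_length=10.0, divisions=1):
    """A single-cable cell of frusta with the given junction radii."""
    n = len(radii) - 1
    segments = []
    for i in range(n):
        segments.append(m.Segment(
            id=str(i),
            proximal=(m.Point3D(0, 0, 0, 2 * radii[0]) if i == 0 else None),
            distal=m.Point3D((i + 1) * seg_length, 0, 0, 2 * radii[i + 1]),
            parent=None if i == 0 else str(i - 1), cable="c"))
    cable = m.Cable(id="c", segment_ids=[str(i) for i in range(n)],
                    internal_divisions=divisions)
    return m.CellMorphology(id="cell", segments=segments,
                            cables=[cable]), cable


def cable_totals(radii, seg_length=10.0):
    """Independent frustum-sum oracle for length/area/axial factor."""
    L = A = R = 0.0
    for r1, r2 in zip(radii, radii[1:]):
        L += seg_length
        A += math.pi * (r1 + r2) * math.hypot(seg_length, r2 - r1)
        R += seg_length / (math.pi * r1 * r2)
    return L, A, R


# ---------------------------------------------------------------------------
# integrity
# ---------------------------------------------------------------------------

class TestIntegrity:
    def test_single_spherical_soma_is_clean(self):
        cell = sphere_morphology("s", 20.0)
        assert m.check_integrity(cell) == []

    def test_displaced_child_is_a_discontinuity(self):
        cell, _ = straight_cable_cell([1.0, 1.0, 1.0])
        # child declares an explicit proximal point 1 um off the parent tip
        cell.segments[1].proximal = m.Point3D(10.0, 1.0, 0.0, 2.0)
        findings = m.check_integrity(cell)
        assert [f.kind for f in findings] == ["discontinuity"]
        assert findings[0].element == "1"

    def test_isolated_segment_in_three_segment_cell(self):
        cell, _ = straight_cable_cell([1.0, 1.0, 1.0])
        cell.segments.append(m.Segment(
            id="lonely", proximal=m.Point3D(99, 99, 99, 2),
            distal=m.Point3D(99, 99, 109, 2), cable="c2"))
        cell.cables.append(m.Cable(id="c2", segment_ids=["lonely"]))
        findings = [f for f in m.check_integrity(cell)
                    if f.kind == "isolated-element"]
        assert len(findings) == 1 and findings[0].element == "lonely"

    def test_zero_length_segment_outside_soma_is_flagged(self):
        cell, _ = straight_cable_cell([1.0, 1.0, 1.0])
        cell.segments[1].distal = m.Point3D(10.0, 0.0, 0.0, 2.0)
        kinds = [f.kind for f in m.check_integrity(cell)]
        assert kinds == ["zero-length"]

    def test_parent_cycle_is_detected(self):
        cell, _ = straight_cable_cell([1.0, 1.0, 1.0])
        cell.segments[0].parent = "1"   # 0 -> 1 -> 0
        kinds = {f.kind for f in m.check_integrity(cell)}
        assert "cycle" in kinds

    def test_findings_survive_a_serialization_round_trip(self):
        from nml1.io import parse_document, serialize_document, \
            NeuroMLDocument
        cell, _ = straight_cable_cell([1.0, 1.0, 1.0])
        cell.segments[1].proximal = m.Point3D(10.0, 1.0, 0.0, 2.0)
        doc = NeuroMLDocument(level=1, cells=[cell])
        doc2 = parse_document(serialize_document(doc))
        before = [(f.kind, f.element) for f in m.check_integrity(cell)]
        after = [(f.kind, f.element)
                 for f in m.check_integrity(doc2.cells[0])]
        assert before == after


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestPathDistance:
    def test_root_at_fraction_zero(self):
        cell = ball_and_stick_morphology()
        assert m.path_distance(cell, "0", 0.0) == 0.0

    def test_ball_and_stick_tip_is_100_um(self):
        """Five collinear 20 um segments; the spherical soma contributes
        zero, so the distal tip sits at 5 x 20 = 100 um (hand sum)."""
        cell = ball_and_stick_morphology()
        assert m.path_distance(cell, "5", 1.0) == pytest.approx(100.0)

    def test_half_way_along_terminal_segment(self):
        cell = ball_and_stick_morphology()
        assert m.path_distance(cell, "5", 0.5) == pytest.approx(90.0)

    def test_monotone_in_fraction_and_additive(self):
        cell = ball_and_stick_morphology()
        ds = [m.path_distance(cell, "3", f) for f in np.linspace(0, 1, 9)]
        assert all(b > a for a, b in zip(ds, ds[1:]))
        # additivity: distance to seg 3 start == distance to seg 2 end
        assert m.path_distance(cell, "3", 0.0) == \
            pytest.approx(m.path_distance(cell, "2", 1.0))

    def test_unknown_segment_raises(self):
        cell = ball_and_stick_morphology()
        with pytest.raises(m.MorphologyError):
            m.path_distance(cell, "nope", 0.5)


class TestVariableDensity:
    def test_constant_expression_is_uniform(self):
        cell = ball_and_stick_morphology()
        vp = m.VariableParameter("gmax", "path-distance-from-soma", "7.5",
                                 applies_to={"dendrite_group"})
        for sid in ("1", "3", "5"):
            assert m.evaluate_density(vp, cell, sid, 0.5) == 7.5

    def test_affine_form_at_origin_and_midpoint(self):
        cell = ball_and_stick_morphology()
        vp = m.VariableParameter("gmax", "path-distance-from-soma",
                                 "0.5 + 0.01*d", applies_to={"all"})
        assert vp.evaluate(0.0) == pytest.approx(0.5)
        # midpoint of the distal segment: d = 90 um (closed-form oracle)
        assert m.evaluate_density(vp, cell, "5", 0.5) == \
            pytest.approx(0.5 + 0.01 * 90.0)

    def test_segment_outside_groups_is_an_error(self):
        cell = ball_and_stick_morphology()
        vp = m.VariableParameter("gmax", "path-distance-from-soma", "1.0",
                                 applies_to={"dendrite_group"})
        with pytest.raises(m.MorphologyError):
            m.evaluate_density(vp, cell, "0", 0.5)   # soma segment


# ---------------------------------------------------------------------------
# recompartmentalization
# ---------------------------------------------------------------------------

class TestRecompartmentalize:
    def test_twenty_segments_four_divisions_gives_four_compartments(self):
        cell, cable = straight_cable_cell([1.0] * 21, divisions=4)
        assert len(cable.segment_ids) == 20
        cyls = m.recompartmentalize(cable, cell)
        assert len(cyls) == 4

    def test_uniform_cylinder_identity(self):
        cell, cable = straight_cable_cell([1.5, 1.5], seg_length=30.0,
                                          divisions=1)
        (cyl,) = m.recompartmentalize(cable, cell)
        assert cyl.length == pytest.approx(30.0)
        assert cyl.radius == pytest.approx(1.5)
        assert cyl.axial_resistance_factor == \
            pytest.approx(30.0 / (math.pi * 1.5 ** 2))
        assert cyl.axial_residual == pytest.approx(0.0, abs=1e-12)

    def test_two_frustum_taper_conserves_all_three(self):
        radii = [2.0, 1.2, 0.6]
        cell, cable = straight_cable_cell(radii, divisions=2)
        cyls = m.recompartmentalize(cable, cell)
        assert len(cyls) == 2
        L, A, R = cable_totals(radii)
        # numeric-integration oracle for the same quantities
        s = np.linspace(0, 20.0, 200001)
        r = np.interp(s, [0, 10, 20], radii)
        A_num = np.trapezoid(
            2 * math.pi * r * np.sqrt(1 + np.gradient(r, s) ** 2), s)
        R_num = np.trapezoid(1.0 / (math.pi * r ** 2), s)
        assert A == pytest.approx(A_num, rel=1e-5)
        assert R == pytest.approx(R_num, rel=1e-5)
        assert sum(c.length for c in cyls) == pytest.approx(L, rel=1e-12)
        assert sum(c.area for c in cyls) == pytest.approx(A, rel=1e-12)
        assert sum(c.axial_resistance_factor for c in cyls) == \
            pytest.approx(R, rel=1e-12)

    def test_sphere_maps_to_single_spherical_compartment(self):
        cell = sphere_morphology("s", 20.0)
        (cyl,) = m.recompartmentalize(cell.cables[0], cell)
        assert cyl.is_sphere
        assert cyl.area == pytest.approx(math.pi * 400.0)
        assert cyl.axial_resistance_factor == 0.0

    def test_zero_length_cable_raises(self):
        # a two-segment cable whose points all coincide is not a sphere
        # and carries no integrable length
        cell, cable = straight_cable_cell([1.0, 1.0, 1.0])
        for seg in cell.segments:
            seg.distal = m.Point3D(0, 0, 0, 2.0)
            if seg.proximal is not None:
                seg.proximal = m.Point3D(0, 0, 0, 2.0)
        with pytest.raises(m.MorphologyError):
            m.recompartmentalize(cable, cell)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(radii=st.lists(st.floats(min_value=0.2, max_value=5.0),
                          min_size=2, max_size=8),
           divisions=st.integers(min_value=1, max_value=7))
    def test_conservation_on_random_tapered_cables(self, radii, divisions):
        """Length, lateral area and integrated axial resistance are each
        conserved to 1e-9 relative for arbitrary tapered cables."""
        cell, cable = straight_cable_cell(radii, divisions=divisions)
        cyls = m.recompartmentalize(cable, cell)
        assert len(cyls) == divisions
        L, A, R = cable_totals(radii)
        assert sum(c.length for c in cyls) == pytest.approx(L, rel=1e-9)
        assert sum(c.area for c in cyls) == pytest.approx(A, rel=1e-9)
        assert sum(c.axial_resistance_factor for c in cyls) == \
            pytest.approx(R, rel=1e-9)
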