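"""Neuronal morphologies: segments, cables, integrity checks and
recompartmentalization.

A cell is a forest of frustum-shaped *segments* (3D proximal/distal points
with diameters) grouped into unbranched *cables*.  Each cable carries an
``internal_divisions`` count (NEURON's ``nseg``) that fixes how finely it
is discretized for simulation.  This module provides:

* structural integrity checking (discontinuities, isolated elements,
  zero-length segments, cycles);
* path-distance and radial-distance metrics used by non-uniform channel
  density expressions;
* the mapping of a cable onto ``internal_divisions`` equivalent cylinders
  that conserve total length, lateral surface area and integrated axial
  resistance.

Conventions (documented, since the exchange format itself fixes neither):
``fraction_along`` is 0 at a segment's proximal point and 1 at its distal
point; path distance is measured from the root segment's proximal point; a
spherical soma (a single segment whose proximal and distal points coincide)
contributes zero to path distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .expressions import Expression
from .meta import Metadata

#: geometric tolerance (um) below which two 3D points are "the same"
POINT_TOL = 1e-6
#: radii are clamped to this floor (um) inside 1/r integrals
MIN_RADIUS = 1e-6


class MorphologyError(ValueError):
    pass


@dataclass(frozen=True)
class Point3D:
    x: float
    y: float
    z: float
    diameter: float

    def distance_to(self, other: "Point3D") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class Segment:
    id: str
    distal: Point3D
    proximal: Optional[Point3D] = None   # None => inherit parent's distal
    parent: Optional[str] = None
    cable: str = ""
    name: str = ""


@dataclass
class Cable:
    id: str
    name: str = ""
    segment_ids: list[str] = field(default_factory=list)
    groups: set[str] = field(default_factory=set)
    internal_divisions: int = 1


@dataclass
class CellMorphology:
    id: str
    segments: list[Segment] = field(default_factory=list)
    cables: list[Cable] = field(default_factory=list)
    metadata: Metadata = field(default_factory=Metadata)

    # -- lookups ---------------------------------------------------------

    def segment_map(self) -> dict[str, Segment]:
        return {s.id: s for s in self.segments}

    def cable_map(self) -> dict[str, Cable]:
        return {c.id: c for c in self.cables}

    def children_map(self) -> dict[Optional[str], list[Segment]]:
        out: dict[Optional[str], list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.parent, []).append(s)
        return out

    def root(self) -> Segment:
        roots = [s for s in self.segments if s.parent is None]
        if not roots:
            raise MorphologyError(f"cell {self.id!r} has no root segment")
        return roots[0]

    def resolved_proximal(self, segment: Segment) -> Point3D:
        if segment.proximal is not None:
            return segment.proximal
        if segment.parent is None:
            raise MorphologyError(
                f"root segment {segment.id!r} has no explicit proximal point")
        return self.segment_map()[segment.parent].distal

    def segment_length(self, segment: Segment) -> float:
        return self.resolved_proximal(segment).distance_to(segment.distal)

    def segment_groups(self, segment_id: str) -> set[str]:
        seg = self.segment_map()[segment_id]
        cable = self.cable_map().get(seg.cable)
        groups = set(cable.groups) if cable else set()
        groups.add("all")
        return groups

    def is_spherical(self, cable: Cable) -> bool:
        """A single zero-length segment with coincident end points."""
        if len(cable.segment_ids) != 1:
            return False
        seg = self.segment_map()[cable.segment_ids[0]]
        prox = self.resolved_proximal(seg)
        return prox.distance_to(seg.distal) < POINT_TOL and seg.distal.diameter > 0

    def surface_area(self) -> float:
        """Total membrane area (um^2): frustum slant areas, spheres pi*d^2."""
        total = 0.0
        segmap = self.segment_map()
        for cable in self.cables:
            if self.is_spherical(cable):
                d = segmap[cable.segment_ids[0]].distal.diameter
                total += math.pi * d * d
            else:
                for sid in cable.segment_ids:
                    seg = segmap[sid]
                    prox = self.resolved_proximal(seg)
                    total += _frustum_area(self.segment_length(seg),
                                           prox.radius, seg.distal.radius)
        return total


def _frustum_area(length: float, r_a: float, r_b: float) -> float:
    slant = math.hypot(length, r_b - r_a)
    return math.pi * (r_a + r_b) * slant


# ---------------------------------------------------------------------------
# integrity checking
# ---------------------------------------------------------------------------

FINDING_KINDS = ("discontinuity", "isolated-element", "zero-length", "cycle")


@dataclass(frozen=True)
class IntegrityFinding:
    kind: str
    element: str          # segment id
    message: str


def check_integrity(cell: CellMorphology) -> list[IntegrityFinding]:
    """Scan a morphology for the four structural defect categories.

    Returns an empty list for a connected, continuous cell.  Zero-length
    segments are tolerated only as spherical somas (single-segment cable
    with coincident endpoints and positive diameter).
    """
    findings: list[IntegrityFinding] = []
    segmap = cell.segment_map()
    children = cell.children_map()

    # cycles: walk parent chains
    in_cycle: set[str] = set()
    state: dict[str, int] = {}  # 0 visiting, 1 done
    for seg in cell.segments:
        chain = []
        cur: Optional[Segment] = seg
        while cur is not None and cur.id not in state:
            state[cur.id] = 0
            chain.append(cur.id)
            cur = segmap.get(cur.parent) if cur.parent is not None else None
            if cur is not None and state.get(cur.id) == 0:
                # found a back-edge: everything from cur onwards is cyclic
                idx = chain.index(cur.id) if cur.id in chain else 0
                in_cycle.update(chain[idx:])
                cur = None
        for cid in chain:
            state[cid] = 1
    for sid in sorted(in_cycle):
        findings.append(IntegrityFinding(
            "cycle", sid, f"segment {sid!r} participates in a parent cycle"))

    # connectivity: components reachable from the first root
    roots = [s for s in cell.segments if s.parent is None]
    reachable: set[str] = set()
    if roots:
        stack = [roots[0].id]
        while stack:
            sid = stack.pop()
            if sid in reachable:
                continue
            reachable.add(sid)
            stack.extend(c.id for c in children.get(sid, []))
    detached_roots = [s for s in roots[1:]] + [
        s for s in cell.segments
        if s.parent is not None and s.parent not in segmap]
    for seg in detached_roots:
        if seg.id in in_cycle:
            continue
        findings.append(IntegrityFinding(
            "isolated-element", seg.id,
            f"segment {seg.id!r} is not connected to the root"))

    # discontinuities: explicit proximal point away from parent's distal
    for seg in cell.segments:
        if seg.proximal is None or seg.parent is None:
            continue
        parent = segmap.get(seg.parent)
        if parent is None:
            continue
        gap = seg.proximal.distance_to(parent.distal)
        if gap > POINT_TOL:
            findings.append(IntegrityFinding(
                "discontinuity", seg.id,
                f"proximal point of {seg.id!r} is {gap:.6g} um from the "
                f"distal point of its parent {seg.parent!r}"))

    # zero-length segments outside spherical somas
    cabmap = cell.cable_map()
    for seg in cell.segments:
        if seg.id in in_cycle or (seg.parent is not None
                                  and seg.parent not in segmap):
            continue
        try:
            length = cell.segment_length(seg)
        except MorphologyError:
            continue
        cable = cabmap.get(seg.cable)
        spherical = cable is not None and cell.is_spherical(cable)
        if length < POINT_TOL and not spherical:
            findings.append(IntegrityFinding(
                "zero-length", seg.id,
                f"segment {seg.id!r} has zero length and is not a "
                f"spherical soma"))

    order = {s.id: i for i, s in enumerate(cell.segments)}
    findings.sort(key=lambda f: (order.get(f.element, len(order)),
                                 FINDING_KINDS.index(f.kind)))
    return findings


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def path_distance(cell: CellMorphology, segment_id: str,
                  fraction_along: float = 1.0) -> float:
    """3D arc length (um) from the root's proximal point to the point
    ``fraction_along`` of the way along ``segment_id``.

    Spherical somas have zero arc length, so they contribute nothing.
    """
    segmap = cell.segment_map()
    if segment_id not in segmap:
        raise MorphologyError(f"unknown segment id {segment_id!r}")
    if not 0.0 <= fraction_along <= 1.0:
        raise MorphologyError("fraction_along must lie in [0, 1]")
    seg = segmap[segment_id]
    dist = fraction_along * cell.segment_length(seg)
    seen = {segment_id}
    cur = seg
    while cur.parent is not None:
        cur = segmap[cur.parent]
        if cur.id in seen:
            raise MorphologyError("cycle encountered on path to root")
        seen.add(cur.id)
        dist += cell.segment_length(cur)
    return dist


def radial_distance(cell: CellMorphology, segment_id: str,
                    fraction_along: float = 1.0) -> float:
    """Straight-line 3D distance (um) from the root's proximal point."""
    segmap = cell.segment_map()
    if segment_id not in segmap:
        raise MorphologyError(f"unknown segment id {segment_id!r}")
    seg = segmap[segment_id]
    prox = cell.resolved_proximal(seg)
    f = fraction_along
    point = (prox.x + f * (seg.distal.x - prox.x),
             prox.y + f * (seg.distal.y - prox.y),
             prox.z + f * (seg.distal.z - prox.z))
    origin = cell.resolved_proximal(cell.root())
    return math.dist(point, (origin.x, origin.y, origin.z))


# ---------------------------------------------------------------------------
# biophysical placement
# ---------------------------------------------------------------------------

METRICS = ("path-distance-from-soma", "3D-radial-distance")


@dataclass
class VariableParameter:
    """A parameter expressed as a function of a spatial metric.

    ``expression`` is an arithmetic expression in the metric variable
    ``d`` (um), e.g. ``"0.5 + 0.01*d"`` for a density rising linearly
    with path distance from the soma.
    """

    parameter_name: str
    metric: str
    expression: str
    applies_to: set[str] = field(default_factory=lambda: {"all"})

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise MorphologyError(f"unknown metric {self.metric!r}")
        self._compiled = Expression(self.expression, variables=("d",))

    def evaluate(self, d: float) -> float:
        value = float(self._compiled(d=d))
        if not math.isfinite(value) or value < 0:
            raise MorphologyError(
                f"variable parameter {self.parameter_name!r} evaluated to "
                f"{value!r} at d={d:g} um; must be finite and non-negative")
        return value


def evaluate_density(placement: VariableParameter, cell: CellMorphology,
                     segment_id: str, fraction_along: float = 0.5) -> float:
    """Evaluate a non-uniform density at a point on the cell (mS/cm^2)."""
    groups = cell.segment_groups(segment_id)
    if not groups & placement.applies_to:
        raise MorphologyError(
            f"segment {segment_id!r} (groups {sorted(groups)}) is outside "
            f"the placement's groups {sorted(placement.applies_to)}")
    if placement.metric == "path-distance-from-soma":
        d = path_distance(cell, segment_id, fraction_along)
    else:
        d = radial_distance(cell, segment_id, fraction_along)
    return placement.evaluate(d)


@dataclass
class ChannelPlacement:
    """Uniform or variable channel density on a set of cable groups."""

    channel_id: str
    density: float | VariableParameter   # mS/cm^2 or an expression thereof
    groups: set[str] = field(default_factory=lambda: {"all"})


@dataclass
class IonPoolPlacement:
    pool_id: str
    groups: set[str] = field(default_factory=lambda: {"all"})


@dataclass
class BiophysicalCell:
    """A morphology plus passive properties and mechanism placements.

    Per-group quantities (``specific_capacitance`` in uF/cm^2,
    ``axial_resistivity`` in kOhm*cm) are dicts keyed by group label; a
    specific group label overrides the ``"all"`` entry.
    """

    morphology: CellMorphology
    specific_capacitance: dict[str, float] = field(
        default_factory=lambda: {"all": 1.0})
    axial_resistivity: dict[str, float] = field(
        default_factory=lambda: {"all": 0.1})
    mechanism_placements: list[ChannelPlacement] = field(default_factory=list)
    ion_pool_placements: list[IonPoolPlacement] = field(default_factory=list)
    connectivity: dict[str, set[str]] = field(default_factory=dict)
    #: synapse id -> allowed group labels (empty dict = unrestricted)

    @property
    def id(self) -> str:
        return self.morphology.id

    def group_value(self, table: dict[str, float], segment_id: str) -> float:
        groups = self.morphology.segment_groups(segment_id)
        for label, value in table.items():
            if label != "all" and label in groups:
                return value
        if "all" in table:
            return table["all"]
        raise MorphologyError(
            f"no value covers segment {segment_id!r} (groups {sorted(groups)})")


# ---------------------------------------------------------------------------
# recompartmentalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalentCylinder:
    """One compartment of a recompartmentalized cable.

    ``axial_resistance_factor`` is the integrated axial resistance per
    unit resistivity, i.e. the exact integral of ``ds / (pi r(s)^2)`` over
    the span (um^-1); multiply by the axial resistivity to obtain ohms.
    ``radius`` is chosen so the cylinder's lateral area ``2 pi r L``
    equals the span's frustum area exactly; ``axial_residual`` records the
    difference between the geometric cylinder's resistance factor
    ``L / (pi r^2)`` and the carried exact value.
    """

    length: float                   # um
    radius: float                   # um
    axial_resistance_factor: float  # 1/um
    area: float                     # um^2
    axial_residual: float           # 1/um
    is_sphere: bool = False


def _piece_area(dl: float, r_a: float, r_b: float) -> float:
    return math.pi * (r_a + r_b) * math.hypot(dl, r_b - r_a)


def _piece_axial(dl: float, r_a: float, r_b: float) -> float:
    r_a = max(r_a, MIN_RADIUS)
    r_b = max(r_b, MIN_RADIUS)
    return dl / (math.pi * r_a * r_b)


def _piece_weight(dl: float, r_a: float, r_b: float) -> float:
    # integral of ds / sqrt(r(s)) for r linear in s
    r_a = max(r_a, MIN_RADIUS)
    r_b = max(r_b, MIN_RADIUS)
    if abs(r_b - r_a) < 1e-15:
        return dl / math.sqrt(r_a)
    m = (r_b - r_a) / dl
    return 2.0 * (math.sqrt(r_b) - math.sqrt(r_a)) / m


def _invert_weight(target_w: float, dl: float, r_a: float, r_b: float) -> float:
    """Arc position s in [0, dl] where the weight integral reaches target."""
    r_a = max(r_a, MIN_RADIUS)
    r_b = max(r_b, MIN_RADIUS)
    if abs(r_b - r_a) < 1e-15:
        return target_w * math.sqrt(r_a)
    m = (r_b - r_a) / dl
    sqrt_r = math.sqrt(r_a) + m * target_w / 2.0
    return (sqrt_r * sqrt_r - r_a) / m


def recompartmentalize(cable: Cable, cell: CellMorphology,
                       ) -> list[EquivalentCylinder]:
    """Map a cable onto ``internal_divisions`` equivalent cylinders.

    The cable is divided into spans of equal electrotonic weight (equal
    increments of the integral of ``ds / sqrt(r)``, the length-constant
    proxy; equal arc length for untapered cables).  Each span becomes one
    cylinder conserving the span's arc length, lateral surface area and
    integrated axial resistance; summed over spans, all three cable totals
    are conserved to machine precision.
    """
    n = cable.internal_divisions
    if n < 1:
        raise MorphologyError("internal_divisions must be >= 1")
    segmap = cell.segment_map()

    if cell.is_spherical(cable):
        seg = segmap[cable.segment_ids[0]]
        d = seg.distal.diameter
        return [EquivalentCylinder(length=0.0, radius=d / 2.0,
                                   axial_resistance_factor=0.0,
                                   area=math.pi * d * d,
                                   axial_residual=0.0, is_sphere=True)]

    # (length, r_prox, r_dist) per segment of the chain
    pieces: list[tuple[float, float, float]] = []
    for sid in cable.segment_ids:
        seg = segmap[sid]
        prox = cell.resolved_proximal(seg)
        length = prox.distance_to(seg.distal)
        if length > 0:
            pieces.append((length, prox.radius, seg.distal.radius))
    total_length = sum(p[0] for p in pieces)
    if total_length <= 0:
        raise MorphologyError(f"cable {cable.id!r} has zero length")

    weights = [_piece_weight(*p) for p in pieces]
    total_w = sum(weights)

    # split points: (piece index, s within piece) at each span boundary
    boundaries: list[tuple[int, float]] = []
    for k in range(1, n):
        target = total_w * k / n
        acc = 0.0
        for i, w in enumerate(weights):
            if acc + w >= target or i == len(weights) - 1:
                boundaries.append(
                    (i, _invert_weight(min(target - acc, w), *pieces[i])))
                break
            acc += w

    # accumulate span totals piece by piece
    spans: list[tuple[float, float, float]] = []  # (length, area, axial)
    cur_len = cur_area = cur_ax = 0.0
    b_idx = 0
    for i, (dl, r_a, r_b) in enumerate(pieces):
        s0 = 0.0
        while b_idx < len(boundaries) and boundaries[b_idx][0] == i:
            s1 = max(boundaries[b_idx][1], s0)
            ra = r_a + (r_b - r_a) * s0 / dl
            rb = r_a + (r_b - r_a) * s1 / dl
            cur_len += s1 - s0
            cur_area += _piece_area(s1 - s0, ra, rb)
            cur_ax += _piece_axial(s1 - s0, ra, rb)
            spans.append((cur_len, cur_area, cur_ax))
            cur_len = cur_area = cur_ax = 0.0
            s0 = s1
            b_idx += 1
        ra = r_a + (r_b - r_a) * s0 / dl
        cur_len += dl - s0
        cur_area += _piece_area(dl - s0, ra, r_b)
        cur_ax += _piece_axial(dl - s0, ra, r_b)
    spans.append((cur_len, cur_area, cur_ax))

    out: list[EquivalentCylinder] = []
    for length, area, axial in spans:
        radius = area / (2.0 * math.pi * length)
        geom_factor = length / (math.pi * radius * radius)
        out.append(EquivalentCylinder(
            length=length, radius=radius, axial_resistance_factor=axial,
            area=area, axial_residual=geom_factor - axial))
    return out
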