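"""NetworkML: populations, projections and inputs.

Networks come in two flavours: *instance-based* (explicit 3D positions and
connection lists -- compact because a homogeneous population stores one
cell description and N locations) and *template-based* (generative rules
plus a seed).  Template support covers uniform random placement in a box
or cylinder and three connection rules (per-cell count, all-to-all, fixed
probability), mirroring the limited template range of the v1.x dialect.

Instantiation and connection are pure functions of (template, seed): the
random stream is keyed by (seed, element name) so adding a population or
projection never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .morphology import BiophysicalCell, CellMorphology


class NetworkError(ValueError):
    pass


def _rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-element generator keyed by (seed, label)."""
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# regions and placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    x: float
    y: float
    z: float
    width: float    # extent along x (um)
    height: float   # extent along y
    depth: float    # extent along z

    def sample(self, rng: np.random.Generator) -> tuple[float, float, float]:
        u = rng.random(3)
        return (self.x + u[0] * self.width,
                self.y + u[1] * self.height,
                self.z + u[2] * self.depth)

    def contains(self, x: float, y: float, z: float, tol: float = 1e-9) -> bool:
        return (self.x - tol <= x <= self.x + self.width + tol
                and self.y - tol <= y <= self.y + self.height + tol
                and self.z - tol <= z <= self.z + self.depth + tol)


@dataclass(frozen=True)
class Cylinder:
    """Vertical cylinder: centre of the base at (x, y, z), axis along y."""

    x: float
    y: float
    z: float
    radius: float
    height: float

    def sample(self, rng: np.random.Generator) -> tuple[float, float, float]:
        r = self.radius * np.sqrt(rng.random())
        theta = 2.0 * np.pi * rng.random()
        h = rng.random() * self.height
        return (self.x + r * np.cos(theta), self.y + h,
                self.z + r * np.sin(theta))

    def contains(self, x: float, y: float, z: float, tol: float = 1e-9) -> bool:
        in_disc = (x - self.x) ** 2 + (z - self.z) ** 2 \
            <= (self.radius + tol) ** 2
        return in_disc and self.y - tol <= y <= self.y + self.height + tol


Region = Box | Cylinder

#: retries per cell for minimal-separation rejection sampling
PLACEMENT_RETRY_CAP = 10_000


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass
class CellInstance:
    index: int
    x: float
    y: float
    z: float
    node_id: Optional[int] = None   # parallel-partition hint; parsed and
    #                                 preserved, never affects semantics


@dataclass
class PopulationTemplate:
    count: int
    region: Region
    min_separation: float = 0.0   # um; 0 disables the separation constraint


@dataclass
class Population:
    name: str
    cell_type: str
    instances: list[CellInstance] = field(default_factory=list)
    template: Optional[PopulationTemplate] = None

    def size(self) -> int:
        if self.instances:
            return len(self.instances)
        return self.template.count if self.template else 0


def place_population(pop: Population, seed: int) -> Population:
    """Realize a template population as explicit instances."""
    if pop.template is None:
        return pop
    tpl = pop.template
    rng = _rng(seed, f"population:{pop.name}")
    placed: list[CellInstance] = []
    coords: list[tuple[float, float, float]] = []
    for i in range(tpl.count):
        for _ in range(PLACEMENT_RETRY_CAP):
            x, y, z = tpl.region.sample(rng)
            if tpl.min_separation > 0.0:
                sep2 = tpl.min_separation ** 2
                if any((x - a) ** 2 + (y - b) ** 2 + (z - c) ** 2 < sep2
                       for a, b, c in coords):
                    continue
            break
        else:
            raise NetworkError(
                f"population {pop.name!r}: could not place cell {i} at "
                f"minimal separation {tpl.min_separation} um after "
                f"{PLACEMENT_RETRY_CAP} retries")
        coords.append((x, y, z))
        placed.append(CellInstance(index=i, x=x, y=y, z=z))
    return Population(name=pop.name, cell_type=pop.cell_type,
                      instances=placed, template=None)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Connection:
    pre_cell: int
    post_cell: int
    pre_segment: str = "0"
    pre_fraction: float = 0.5
    post_segment: str = "0"
    post_fraction: float = 0.5
    weight: float = 1.0
    delay: float = 0.0   # ms


@dataclass
class Projection:
    name: str
    source: str
    target: str
    synapse_id: str
    connections: list[Connection] = field(default_factory=list)
    electrical: bool = False
    conductance: Optional[float] = None   # uS, electrical projections only


@dataclass(frozen=True)
class PerCellCount:
    count: int
    allow_multiplicity: bool = False


@dataclass(frozen=True)
class AllToAll:
    allow_self: bool = False


@dataclass(frozen=True)
class FixedProbability:
    p: float


ConnectionRule = PerCellCount | AllToAll | FixedProbability


def _post_site(rng: np.random.Generator,
               target_cell: Optional[BiophysicalCell | CellMorphology],
               groups: Optional[set[str]]) -> tuple[str, float]:
    """Pick a postsynaptic segment respecting allowed connectivity groups."""
    if target_cell is None:
        return "0", 0.5
    morph = (target_cell.morphology
             if isinstance(target_cell, BiophysicalCell) else target_cell)
    if groups:
        candidates = [s.id for s in morph.segments
                      if morph.segment_groups(s.id) & groups]
        if not candidates:
            raise NetworkError(
                f"no segment of cell {morph.id!r} lies in groups "
                f"{sorted(groups)}")
    else:
        candidates = [s.id for s in morph.segments]
    sid = candidates[int(rng.integers(len(candidates)))]
    return sid, float(rng.random())


def connect(source: Population, target: Population, rule: ConnectionRule,
            synapse_id: str, seed: int, name: Optional[str] = None,
            target_cell: Optional[BiophysicalCell | CellMorphology] = None,
            targeting_groups: Optional[set[str]] = None,
            weight: float = 1.0, delay: float = 0.0) -> Projection:
    """Build a chemical projection under a seeded connection rule.

    Self-connections are excluded when source and target are the same
    population (except all-to-all with ``allow_self=True``).
    """
    name = name or f"{source.name}_to_{target.name}"
    rng = _rng(seed, f"projection:{name}")
    n_src, n_tgt = source.size(), target.size()
    same = source.name == target.name
    conns: list[Connection] = []

    def make(pre: int, post: int) -> Connection:
        seg, frac = _post_site(rng, target_cell, targeting_groups)
        return Connection(pre_cell=pre, post_cell=post, post_segment=seg,
                          post_fraction=frac, weight=weight, delay=delay)

    if isinstance(rule, AllToAll):
        for pre in range(n_src):
            for post in range(n_tgt):
                if same and pre == post and not rule.allow_self:
                    continue
                conns.append(make(pre, post))
    elif isinstance(rule, PerCellCount):
        for pre in range(n_src):
            pool = [p for p in range(n_tgt) if not (same and p == pre)]
            if rule.allow_multiplicity:
                picks = rng.integers(len(pool), size=rule.count)
                chosen = [pool[int(i)] for i in picks]
            else:
                if rule.count > len(pool):
                    raise NetworkError(
                        f"projection {name!r}: {rule.count} distinct targets "
                        f"requested but only {len(pool)} available")
                chosen = [pool[int(i)] for i in
                          rng.choice(len(pool), size=rule.count,
                                     replace=False)]
            for post in chosen:
                conns.append(make(pre, post))
    elif isinstance(rule, FixedProbability):
        if not 0.0 <= rule.p <= 1.0:
            raise NetworkError("connection probability must lie in [0, 1]")
        for pre in range(n_src):
            for post in range(n_tgt):
                if same and pre == post:
                    continue
                if rng.random() < rule.p:
                    conns.append(make(pre, post))
    else:  # pragma: no cover - exhaustive over rule union
        raise NetworkError(f"unknown connection rule {rule!r}")

    return Projection(name=name, source=source.name, target=target.name,
                      synapse_id=synapse_id, connections=conns)


def attach_gap_junctions(pop: Population, rule: ConnectionRule,
                         synapse_id: str, conductance: float, seed: int,
                         name: Optional[str] = None) -> Projection:
    """Electrical connections within a population; each unordered pair is
    stored once (pre < post) and every connection carries the same
    conductance (uS)."""
    name = name or f"{pop.name}_gap_junctions"
    rng = _rng(seed, f"projection:{name}")
    n = pop.size()
    pairs: list[tuple[int, int]] = []
    if isinstance(rule, AllToAll):
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif isinstance(rule, FixedProbability):
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < rule.p:
                    pairs.append((i, j))
    elif isinstance(rule, PerCellCount):
        for i in range(n):
            pool = [j for j in range(n) if j != i]
            if rule.count > len(pool):
                raise NetworkError(
                    f"{name!r}: cannot pick {rule.count} partners from "
                    f"{len(pool)} cells")
            for j in rng.choice(len(pool), size=rule.count, replace=False):
                a, b = sorted((i, pool[int(j)]))
                if (a, b) not in pairs:
                    pairs.append((a, b))
    else:  # pragma: no cover
        raise NetworkError(f"unknown connection rule {rule!r}")
    conns = [Connection(pre_cell=a, post_cell=b) for a, b in pairs]
    return Projection(name=name, source=pop.name, target=pop.name,
                      synapse_id=synapse_id, connections=conns,
                      electrical=True, conductance=conductance)


# ---------------------------------------------------------------------------
# inputs and the network containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkInput:
    """External drive applied to a population (or listed cells).

    kinds: ``current-pulse`` (fixed amplitude, delay, duration),
    ``continuous-random-current`` (per-cell amplitude drawn once from
    [amplitude_min, amplitude_max], applied for the whole run) and
    ``random-synaptic-events`` (Poisson events at ``rate`` through
    ``synapse_id``).
    """

    name: str
    kind: str
    target_population: str
    amplitude: float = 0.0        # nA (current-pulse)
    amplitude_min: float = 0.0    # nA (random current)
    amplitude_max: float = 0.0
    delay: float = 0.0            # ms
    duration: float = 0.0         # ms
    rate: float = 0.0             # Hz (random synaptic events)
    synapse_id: str = ""
    segment: str = "0"
    fraction: float = 0.5
    cells: Optional[list[int]] = None   # None = whole population

    KINDS = ("current-pulse", "continuous-random-current",
             "random-synaptic-events")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise NetworkError(f"unknown input kind {self.kind!r}")
        if self.rate < 0 or self.amplitude_max < self.amplitude_min:
            raise NetworkError("input rates/amplitude ranges must be valid")


@dataclass
class NetworkInstance:
    populations: list[Population] = field(default_factory=list)
    projections: list[Projection] = field(default_factory=list)
    inputs: list[NetworkInput] = field(default_factory=list)

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise NetworkError(f"unknown population {name!r}")


@dataclass
class NetworkTemplate(NetworkInstance):
    seed: int = 0


def instantiate(template: NetworkTemplate,
                seed: Optional[int] = None) -> NetworkInstance:
    """Realize all template populations; projections/inputs pass through."""
    use_seed = template.seed if seed is None else seed
    pops = [place_population(p, use_seed) for p in template.populations]
    return NetworkInstance(populations=pops,
                           projections=list(template.projections),
                           inputs=list(template.inputs))
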