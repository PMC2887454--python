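"""Reference compartmental simulator for branched cable models.

A :class:`~nml1.morphology.BiophysicalCell` is discretized cable-by-cable
into equivalent cylinders (see :func:`nml1.morphology.recompartmentalize`)
under one of two symmetry conventions:

* ``symmetric`` -- half of each compartment's axial resistance sits at
  each end and the voltage is computed at the compartment centre;
* ``asymmetric`` -- all of the axial resistance sits on the proximal side
  and the voltage is computed at the distal node.

Both conventions converge to the same cable-equation solution as the
spatial discretisation is refined; comparing them at finite resolution is
the cross-solver convergence methodology this package implements
(:func:`compare_runs`, spike-time discrepancy as a percentage of run time).

The voltage is advanced by an implicit (backward-Euler) solve over the
whole compartment tree each step, with channel conductances frozen at the
current gate states; gates are then advanced by the exact exponential
update toward their steady state, and Ca2+ pools by their exact
first-order update.  A semi-implicit second-order (Crank-Nicolson) option
exists for convergence studies.  Explicit exponential-Euler integration is
deliberately not offered: it needs time steps orders of magnitude smaller
for the same accuracy.

Internal units: mV, ms, um, uS, nA, nF, MOhm (so uS*mV = nA and
nF*mV/ms = nA are consistent without conversion factors).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import channels as ch
from . import synapses as syn
from .morphology import (BiophysicalCell, Cable, CellMorphology,
                         EquivalentCylinder, VariableParameter,
                         path_distance, radial_distance,
                         recompartmentalize)
from .network import Projection

#: MOhm per (kOhm*cm resistivity * um^-1 geometry factor)
RESISTANCE_SCALE = 10.0
#: nF of capacitance per (uF/cm^2 * um^2)
CAP_TO_NF = 1e-5
#: divergence guard (mV)
V_LIMIT = 1000.0


class SimulationError(RuntimeError):
    pass


class DivergenceError(SimulationError):
    pass


@dataclass
class SolverConfig:
    dt: float = 0.01                     # ms
    symmetry: str = "symmetric"          # or "asymmetric"
    temperature: Optional[float] = None  # degC; None disables Q10 scaling
    method: str = "implicit-first-order"  # or "semi-implicit-second-order"
    seed: int = 0
    initial_voltage: float = -65.0       # mV
    spike_threshold: float = 0.0         # mV

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise SimulationError("dt must be positive")
        if self.symmetry not in ("symmetric", "asymmetric"):
            raise SimulationError(f"unknown symmetry {self.symmetry!r}")
        if self.method not in ("implicit-first-order",
                               "semi-implicit-second-order"):
            raise SimulationError(f"unknown method {self.method!r}")

    @property
    def theta(self) -> float:
        return 1.0 if self.method == "implicit-first-order" else 0.5


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

Target = tuple[int, str, float]   # (cell index, segment id, fraction_along)


@dataclass
class CurrentPulse:
    target: Target
    amplitude: float   # nA
    delay: float = 0.0
    duration: float = 1e12


@dataclass
class RandomCurrent:
    """Continuous current injection of random amplitude: one draw per run
    from [amplitude_min, amplitude_max], held constant."""

    target: Target
    amplitude_min: float
    amplitude_max: float
    name: str = "random_current"


@dataclass
class SynapticEvents:
    """Synaptic events onto a target: explicit times, or Poisson at
    ``rate`` (Hz) when ``times`` is None."""

    target: Target
    synapse_id: str
    times: Optional[Sequence[float]] = None   # ms
    rate: float = 0.0
    weight: float = 1.0
    name: str = "synaptic_events"


@dataclass
class VoltageClamp:
    """Pin a node's voltage to a piecewise-constant schedule
    [(start time, level mV), ...] and record the clamp current."""

    target: Target
    levels: Sequence[tuple[float, float]]

    def level_at(self, t: float) -> float:
        lvl = self.levels[0][1]
        for start, value in self.levels:
            if t >= start:
                lvl = value
        return lvl


Stimulus = CurrentPulse | RandomCurrent | SynapticEvents | VoltageClamp


# ---------------------------------------------------------------------------
# compartment graph
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    index: int
    cell_index: int
    cable_id: str
    span: int
    geometry: EquivalentCylinder
    cm: float                    # nF
    parent: int                  # -1 for a root
    link_resistance: float       # MOhm to parent (0 for roots)


@dataclass
class CompartmentGraph:
    comps: list[Compartment]
    parent: np.ndarray           # int, -1 at roots
    link_g: np.ndarray           # uS to parent
    cm: np.ndarray               # nF
    area: np.ndarray             # um^2
    #: mechanism id -> (compartment indices, absolute conductances uS)
    placements: dict[str, tuple[np.ndarray, np.ndarray]]
    #: pool id -> compartment indices
    pool_sites: dict[str, np.ndarray]
    #: per cell: (cell id, first compartment, count, root compartment)
    cells: list[tuple[str, int, int, int]]
    #: (cell index, cable id) -> (first comp index, span end arc lengths)
    cable_index: dict[tuple[int, str], tuple[int, np.ndarray]]
    #: (cell index, segment id) -> (cable id, arc offset of segment start)
    segment_arc: dict[tuple[int, str], tuple[str, float]]
    symmetry: str

    @property
    def n(self) -> int:
        return len(self.comps)

    def locate(self, cell_index: int, segment_id: str,
               fraction: float = 0.5) -> int:
        """Compartment index containing a (segment, fraction) point."""
        key = (cell_index, segment_id)
        if key not in self.segment_arc:
            raise SimulationError(
                f"cell {cell_index}: unknown segment {segment_id!r}")
        cable_id, start_arc = self.segment_arc[key]
        first, ends = self.cable_index[(cell_index, cable_id)]
        seg_len = self._segment_lengths[key]
        arc = start_arc + fraction * seg_len
        span = int(np.searchsorted(ends, arc + 1e-12))
        return first + min(span, len(ends) - 1)

    _segment_lengths: dict[tuple[int, str], float] = field(
        default_factory=dict, repr=False)

    def axial_laplacian(self) -> np.ndarray:
        """Dense conductance Laplacian L (uS): (L @ V)[i] is the net axial
        current leaving compartment i."""
        n = self.n
        lap = np.zeros((n, n))
        for i in range(n):
            p = int(self.parent[i])
            if p < 0:
                continue
            g = self.link_g[i]
            lap[i, i] += g
            lap[p, p] += g
            lap[i, p] -= g
            lap[p, i] -= g
        return lap


def _cable_order(morph: CellMorphology) -> list[Cable]:
    """Cables ordered root-first so parents are built before children."""
    segmap = morph.segment_map()
    cable_of = {s.id: s.cable for s in morph.segments}
    root_cable = cable_of[morph.root().id]
    depth: dict[str, int] = {root_cable: 0}

    def cable_depth(cab: Cable) -> int:
        if cab.id in depth:
            return depth[cab.id]
        first = segmap[cab.segment_ids[0]]
        if first.parent is None:
            depth[cab.id] = 0
        else:
            parent_cable = cable_of[first.parent]
            depth[cab.id] = 1 + cable_depth(morph.cable_map()[parent_cable])
        return depth[cab.id]

    return sorted(morph.cables, key=cable_depth)


def _centre_metric(cell: BiophysicalCell, cable: Cable, centre_arc: float,
                   metric: str) -> float:
    """Metric value at an arc position along a cable (for variable
    densities evaluated at compartment centres)."""
    morph = cell.morphology
    segmap = morph.segment_map()
    acc = 0.0
    for sid in cable.segment_ids:
        seg_len = morph.segment_length(segmap[sid])
        if acc + seg_len >= centre_arc or sid == cable.segment_ids[-1]:
            frac = 0.0 if seg_len == 0 else \
                min(max((centre_arc - acc) / seg_len, 0.0), 1.0)
            if metric == "path-distance-from-soma":
                return path_distance(morph, sid, frac)
            return radial_distance(morph, sid, frac)
        acc += seg_len
    raise AssertionError("unreachable")


def build_graph(cells: BiophysicalCell | Sequence[BiophysicalCell],
                config: SolverConfig,
                mechanisms: Optional[dict[str, object]] = None,
                ) -> CompartmentGraph:
    """Discretize one or more cells into a compartment graph.

    Per-cable compartment counts equal ``internal_divisions``; axial link
    resistances are placed per ``config.symmetry``; non-uniform channel
    densities are evaluated at each compartment's centre path distance.
    ``mechanisms`` resolves integrate-and-fire placements (their leak
    conductance comes from the mechanism, not the placement density).
    """
    if isinstance(cells, BiophysicalCell):
        cells = [cells]
    mechanisms = mechanisms or {}

    comps: list[Compartment] = []
    placements: dict[str, list[tuple[int, float]]] = {}
    pool_sites: dict[str, list[int]] = {}
    cell_table: list[tuple[str, int, int, int]] = []
    cable_index: dict[tuple[int, str], tuple[int, np.ndarray]] = {}
    segment_arc: dict[tuple[int, str], tuple[str, float]] = {}
    segment_lengths: dict[tuple[int, str], float] = {}

    for ci, cell in enumerate(cells):
        morph = cell.morphology
        segmap = morph.segment_map()
        first_comp = len(comps)
        root_comp = -1
        # per-cable compartment bookkeeping
        comp_R: dict[int, float] = {}
        for cable in _cable_order(morph):
            cyls = recompartmentalize(cable, morph)
            first_seg = segmap[cable.segment_ids[0]]
            ra = cell.group_value(cell.axial_resistivity,
                                  first_seg.id)            # kOhm*cm
            cm_spec = cell.group_value(cell.specific_capacitance,
                                       first_seg.id)       # uF/cm^2
            # attachment: compartment holding the parent segment's distal end
            if first_seg.parent is None:
                attach = -1
            else:
                parent_seg = segmap[first_seg.parent]
                pc_id, pstart = segment_arc[(ci, parent_seg.id)]
                pfirst, pends = cable_index[(ci, pc_id)]
                arc = pstart + segment_lengths[(ci, parent_seg.id)]
                span = int(np.searchsorted(pends, arc - 1e-12))
                attach = pfirst + min(span, len(pends) - 1)

            base = len(comps)
            ends = np.cumsum([c.length for c in cyls])
            cable_index[(ci, cable.id)] = (base, ends)
            acc = 0.0
            for sid in cable.segment_ids:
                segment_arc[(ci, sid)] = (cable.id, acc)
                seg_len = morph.segment_length(segmap[sid])
                segment_lengths[(ci, sid)] = seg_len
                acc += seg_len

            for j, cyl in enumerate(cyls):
                r_comp = cyl.axial_resistance_factor * ra * RESISTANCE_SCALE
                idx = len(comps)
                if j == 0:
                    parent = attach
                else:
                    parent = idx - 1
                if parent < 0:
                    link = 0.0
                elif config.symmetry == "symmetric":
                    link = r_comp / 2.0 + comp_R[parent] / 2.0
                else:
                    link = r_comp if r_comp > 0 else comp_R[parent]
                comps.append(Compartment(
                    index=idx, cell_index=ci, cable_id=cable.id, span=j,
                    geometry=cyl, cm=cm_spec * cyl.area * CAP_TO_NF,
                    parent=parent, link_resistance=link))
                comp_R[idx] = r_comp
                if parent < 0:
                    root_comp = idx

            # mechanism placements on this cable
            groups = morph.segment_groups(first_seg.id)
            for pl in cell.mechanism_placements:
                if not groups & pl.groups:
                    continue
                mech = mechanisms.get(pl.channel_id)
                centre = 0.0
                for j, cyl in enumerate(cyls):
                    centre_arc = ends[j] - cyls[j].length / 2.0
                    if isinstance(pl.density, VariableParameter):
                        d = _centre_metric(cell, cable, centre_arc,
                                           pl.density.metric)
                        dens = pl.density.evaluate(d)
                    elif isinstance(mech, ch.IaFMechanism):
                        dens = mech.leak_conductance
                    else:
                        dens = pl.density
                    g_abs = dens * cyl.area * ch.DENSITY_TO_US
                    placements.setdefault(pl.channel_id, []).append(
                        (base + j, g_abs))
            for pp in cell.ion_pool_placements:
                if groups & pp.groups:
                    pool_sites.setdefault(pp.pool_id, []).extend(
                        range(base, base + len(cyls)))

        cell_table.append((cell.id, first_comp,
                           len(comps) - first_comp, root_comp))

    n = len(comps)
    graph = CompartmentGraph(
        comps=comps,
        parent=np.array([c.parent for c in comps], dtype=int),
        link_g=np.array([0.0 if c.link_resistance <= 0 else
                         1.0 / c.link_resistance for c in comps]),
        cm=np.array([c.cm for c in comps]),
        area=np.array([c.geometry.area for c in comps]),
        placements={k: (np.array([i for i, _ in v], dtype=int),
                        np.array([g for _, g in v]))
                    for k, v in placements.items()},
        pool_sites={k: np.array(sorted(set(v)), dtype=int)
                    for k, v in pool_sites.items()},
        cells=cell_table,
        cable_index=cable_index,
        segment_arc=segment_arc,
        symmetry=config.symmetry)
    graph._segment_lengths = segment_lengths
    assert graph.parent.shape == (n,)
    return graph


# ---------------------------------------------------------------------------
# recordings and spike trains
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    variable: str
    label: str
    dt: float
    samples: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


@dataclass
class SpikeTrain:
    times: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def detect_spikes(trace: np.ndarray, dt: float,
                  threshold: float = 0.0) -> SpikeTrain:
    """Upward threshold crossings, linearly interpolated between samples."""
    v = np.asarray(trace, dtype=float)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return SpikeTrain(times=(idx + frac) * dt)


@dataclass
class RunComparison:
    same_count: bool
    count_a: int
    count_b: int
    max_discrepancy_percent: Optional[float]


def compare_runs(train_a: SpikeTrain, train_b: SpikeTrain,
                 run_time: float) -> RunComparison:
    """Cross-run convergence metric: maximum matched spike-time difference
    as a percentage of the simulation run time.

    Matching is order-based and only defined when spike counts agree; a
    count mismatch is reported, not raised.
    """
    ta, tb = np.asarray(train_a.times), np.asarray(train_b.times)
    if len(ta) != len(tb):
        return RunComparison(False, len(ta), len(tb), None)
    if len(ta) == 0:
        return RunComparison(True, 0, 0, 0.0)
    disc = float(np.max(np.abs(ta - tb))) / run_time * 100.0
    return RunComparison(True, len(ta), len(tb), disc)


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

def _stim_rng(seed: int, label: str) -> np.random.Generator:
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))


class _SynapseSite:
    """Scheduled events through one synapse instance onto one compartment."""

    def __init__(self, comp: int, mechanism, graph_area: float = 0.0):
        self.comp = comp
        self.stp = None
        self.block = None
        if isinstance(mechanism, syn.STPSynapse):
            self.base = mechanism.base
            self.stp = mechanism
            self.stp_state = mechanism.initial_state()
        elif isinstance(mechanism, syn.BlockingSynapse):
            self.base = mechanism.base
            self.block = mechanism.block
        elif isinstance(mechanism, syn.DoubleExpSynapse):
            self.base = mechanism
        else:
            raise SimulationError(
                f"mechanism {mechanism!r} cannot deliver events")
        self.window = (self.base.rise_time
                       + 10.0 * max(self.base.decay_times))
        self.events: list[tuple[float, float]] = []   # (time, scale)
        self._head = 0

    def add_event(self, t: float, weight: float = 1.0) -> None:
        if self.stp is not None:
            release, self.stp_state = self.stp.on_spike(self.stp_state, t)
            weight *= self.stp.event_scale(release)
        self.events.append((t, weight))

    def conductance(self, t: float) -> float:
        g = 0.0
        while (self._head < len(self.events)
               and t - self.events[self._head][0] > self.window):
            self._head += 1
        for te, scale in self.events[self._head:]:
            if te > t:
                break
            g += scale * self.base.conductance_at(t - te)
        return g


@dataclass
class RunResult:
    dt: float
    duration: float
    recordings: dict[str, Recording]
    spike_trains: dict[str, SpikeTrain]

    def voltage(self, label: str) -> np.ndarray:
        return self.recordings[f"v:{label}"].samples

    def spikes(self, label: str) -> SpikeTrain:
        return self.spike_trains[label]


def run(graph: CompartmentGraph, mechanisms: dict[str, object],
        stimuli: Sequence[Stimulus], duration: float, config: SolverConfig,
        projections: Sequence[Projection] = (),
        record: Optional[Sequence[tuple[str, Target]]] = None,
        record_ca: bool = False) -> RunResult:
    """Integrate the compartment graph for ``duration`` ms.

    ``record`` is a list of (label, target) pairs; by default the root
    compartment (soma) of every cell is recorded.  Spike trains are
    detected on every recorded voltage at ``config.spike_threshold``.
    Identical graph + stimuli + config (incl. seed) give bit-identical
    results.
    """
    dt = config.dt
    theta = config.theta
    n = graph.n
    n_steps = int(math.floor(duration / dt + 1e-9))
    if duration <= 0:
        raise SimulationError("duration must be positive")

    # --- resolve mechanisms ------------------------------------------------
    chan_rt = []      # (channel, comp_idx, g_abs, [gate states] | occupancies)
    iaf_rt = []       # (mech, comp_idx, g_abs)
    v = np.full(n, config.initial_voltage)
    for mech_id, (idx, g_abs) in graph.placements.items():
        mech = mechanisms.get(mech_id)
        if mech is None:
            raise SimulationError(f"unresolved mechanism {mech_id!r}")
        if isinstance(mech, ch.IaFMechanism):
            iaf_rt.append([mech, idx, g_abs])
        elif isinstance(mech, ch.ChannelType):
            chan_rt.append([mech, idx, g_abs, None])
        else:
            raise SimulationError(
                f"mechanism {mech_id!r} cannot be placed on the membrane")

    pools_rt = []     # (pool, comp_idx, conc array)
    ca_conc = np.zeros(n)
    for pool_id, idx in graph.pool_sites.items():
        pool = mechanisms.get(pool_id)
        if not isinstance(pool, ch.IonConcentrationModel):
            raise SimulationError(f"unresolved ion pool {pool_id!r}")
        pools_rt.append([pool, idx, np.full(len(idx),
                                            pool.resting_concentration)])
        ca_conc[idx] = pool.resting_concentration

    temp = config.temperature
    _check_grid = np.linspace(-100.0, 60.0, 17)

    # fast per-gate rate closures (validated once over the physiological
    # range; Q10 scaling folded into the closure)
    rate_fns: dict[int, list] = {}
    for entry in chan_rt:
        channel = entry[0]
        q10_scale = channel.q10.factor(temp) if channel.q10 else 1.0
        fns = []
        for gate in channel.gates:
            ch.evaluate_rate(gate.forward, _check_grid, ca=1e-4,
                             temp=temp, q10=channel.q10)
            ch.evaluate_rate(gate.backward, _check_grid, ca=1e-4,
                             temp=temp, q10=channel.q10)
            fns.append((ch.rate_function(gate.forward, q10_scale, temp),
                        ch.rate_function(gate.backward, q10_scale, temp),
                        gate.ligand_gated))
        rate_fns[id(entry)] = fns

    def gate_rates(entry, gate_pos, volts, comp_idx):
        f_alpha, f_beta, ligand = rate_fns[id(entry)][gate_pos]
        ca = ca_conc[comp_idx] if ligand else None
        return (np.asarray(f_alpha(volts, ca)),
                np.asarray(f_beta(volts, ca)))

    # initialize gate states at steady state for the initial voltage
    for entry in chan_rt:
        channel, idx, _, _ = entry
        if channel.scheme is not None:
            n_states = len(channel.scheme.states)
            occ = np.zeros((len(idx), n_states))
            occ[:, 0] = 1.0
            # relax to steady state at V0 with a long exact step
            q = channel.scheme.rate_matrix(config.initial_voltage,
                                           None, temp, channel.q10)
            import scipy.linalg as sla
            prop = sla.expm(q * 1e6)
            occ = occ @ prop
            entry[3] = ("scheme", np.clip(occ, 0.0, 1.0))
        elif channel.gates:
            states = []
            for g_i in range(len(channel.gates)):
                alpha, beta = gate_rates(entry, g_i, v[idx], idx)
                states.append(alpha / (alpha + beta))
            entry[3] = ("gates", states)
        else:
            entry[3] = ("passive", None)

    # --- stimuli ------------------------------------------------------------
    pulses: list[tuple[int, float, float, float]] = []
    clamps: list[tuple[int, VoltageClamp]] = []
    syn_sites: list[_SynapseSite] = []
    for stim in stimuli:
        comp = graph.locate(*stim.target)
        if isinstance(stim, CurrentPulse):
            pulses.append((comp, stim.amplitude, stim.delay,
                           stim.delay + stim.duration))
        elif isinstance(stim, RandomCurrent):
            rng = _stim_rng(config.seed, f"{stim.name}:{stim.target}")
            amp = stim.amplitude_min + rng.random() * (
                stim.amplitude_max - stim.amplitude_min)
            pulses.append((comp, amp, 0.0, duration))
        elif isinstance(stim, SynapticEvents):
            mech = mechanisms.get(stim.synapse_id)
            if mech is None:
                raise SimulationError(
                    f"unresolved synapse {stim.synapse_id!r}")
            site = _SynapseSite(comp, mech)
            if stim.times is not None:
                times = sorted(float(t) for t in stim.times)
            else:
                rng = _stim_rng(config.seed, f"{stim.name}:{stim.target}")
                times = []
                t = 0.0
                rate_ms = stim.rate / 1000.0
                while rate_ms > 0:
                    t += rng.exponential(1.0 / rate_ms)
                    if t >= duration:
                        break
                    times.append(t)
            for t in times:
                site.add_event(t, stim.weight)
            syn_sites.append(site)
        elif isinstance(stim, VoltageClamp):
            clamps.append((comp, stim))

    # --- projections (network runs) -----------------------------------------
    gap_links: list[tuple[int, int, float]] = []
    proj_rt = []   # (pre comp, site, delay) triggered by pre-cell spikes
    for proj in projections:
        if proj.electrical:
            g = proj.conductance if proj.conductance is not None else 0.0
            mech = mechanisms.get(proj.synapse_id)
            if isinstance(mech, syn.GapJunction) and proj.conductance is None:
                g = mech.conductance
            for c in proj.connections:
                a = graph.locate(_cell_index(graph, proj.source, c.pre_cell),
                                 c.pre_segment, c.pre_fraction)
                b = graph.locate(_cell_index(graph, proj.target, c.post_cell),
                                 c.post_segment, c.post_fraction)
                gap_links.append((a, b, g * c.weight))
        else:
            mech = mechanisms.get(proj.synapse_id)
            if mech is None:
                raise SimulationError(
                    f"unresolved synapse {proj.synapse_id!r}")
            for c in proj.connections:
                pre = graph.locate(_cell_index(graph, proj.source,
                                               c.pre_cell),
                                   c.pre_segment, c.pre_fraction)
                site = _SynapseSite(
                    graph.locate(_cell_index(graph, proj.target, c.post_cell),
                                 c.post_segment, c.post_fraction), mech)
                syn_sites.append(site)
                proj_rt.append((pre, site, c.delay, c.weight))

    # --- constant matrix parts ----------------------------------------------
    lap = graph.axial_laplacian()
    for a, b, g in gap_links:
        lap[a, a] += g
        lap[b, b] += g
        lap[a, b] -= g
        lap[b, a] -= g
    cm_dt = graph.cm / dt

    # --- recording ----------------------------------------------------------
    if record is None:
        record = []
        for cell_id, first, count, root in graph.cells:
            record.append((cell_id, None))
    rec_comps: list[tuple[str, int]] = []
    for label, target in record:
        if target is None:
            idx = next(root for cid, first, count, root in graph.cells
                       if cid == label or label.startswith(cid))
        else:
            idx = graph.locate(*target)
        rec_comps.append((label, idx))
    v_store = np.empty((n_steps + 1, len(rec_comps)))
    clamp_store = np.empty((n_steps + 1, len(clamps)))
    ca_store = (np.empty((n_steps + 1, len(pools_rt))) if record_ca else None)

    # IaF state
    refr_until = np.full(n, -1.0)
    iaf_spikes: dict[int, list[float]] = {}
    prev_above = np.zeros(n, dtype=bool)
    iaf_comp_mask = np.zeros(n, dtype=bool)
    for mech, idx, _ in iaf_rt:
        iaf_comp_mask[idx] = True

    def snapshot(step: int, v_now: np.ndarray,
                 clamp_i: Optional[np.ndarray]) -> None:
        for k, (_, comp) in enumerate(rec_comps):
            v_store[step, k] = v_now[comp]
        if clamp_i is not None:
            clamp_store[step, :] = clamp_i
        if ca_store is not None:
            for k, (_, _, conc) in enumerate(pools_rt):
                ca_store[step, k] = conc.mean() if len(conc) else 0.0

    snapshot(0, v, np.zeros(len(clamps)) if clamps else None)

    identity_rows = np.eye(n)
    theta_lap = theta * lap
    diag = np.arange(n)
    # precompute uniqueness of placement indices so the common case can
    # use direct fancy-index accumulation instead of np.add.at
    uniq_flag = {}
    for entry in chan_rt:
        idx = entry[1]
        uniq_flag[id(entry)] = len(np.unique(idx)) == len(idx)
    open_masks = {}
    for entry in chan_rt:
        if entry[0].scheme is not None:
            open_masks[id(entry)] = np.array(
                [s.open for s in entry[0].scheme.states])
    any_pool = bool(pools_rt)

    t = 0.0
    for step in range(1, n_steps + 1):
        t_new = step * dt

        # membrane conductances and reversal-weighted sources at current states
        g_mem = np.zeros(n)
        g_e = np.zeros(n)
        ica_out = np.zeros(n) if any_pool else None
        for entry in chan_rt:
            channel, idx, g_abs, state = entry
            kind, data = state
            if kind == "gates":
                factor = data[0] ** channel.gates[0].instances
                for gate, m in zip(channel.gates[1:], data[1:]):
                    factor = factor * m ** gate.instances
                g_here = g_abs * factor
            elif kind == "scheme":
                factor = data[:, open_masks[id(entry)]].sum(axis=1)
                g_here = g_abs * factor
            else:
                g_here = g_abs
            if uniq_flag[id(entry)]:
                g_mem[idx] += g_here
                g_e[idx] += g_here * channel.reversal_potential
            else:
                np.add.at(g_mem, idx, g_here)
                np.add.at(g_e, idx, g_here * channel.reversal_potential)
            if any_pool and channel.ion == "ca":
                np.add.at(ica_out, idx,
                          g_here * (v[idx] - channel.reversal_potential))
        for mech, idx, g_abs in iaf_rt:
            np.add.at(g_mem, idx, g_abs)
            np.add.at(g_e, idx, g_abs * mech.leak_reversal)

        # synaptic conductances (event-driven), block factors at V^n
        g_syn = np.zeros(n)
        ge_syn = np.zeros(n)
        for site in syn_sites:
            g = site.conductance(t_new)
            if g == 0.0:
                continue
            if site.block is not None:
                g *= site.block.factor(v[site.comp])
            g_syn[site.comp] += g
            ge_syn[site.comp] += g * site.base.reversal

        # external currents
        i_ext = np.zeros(n)
        for comp, amp, t0, t1 in pulses:
            if t0 <= t < t1:
                i_ext[comp] += amp

        g_tot = g_mem + g_syn
        rhs = cm_dt * v + g_e + ge_syn + i_ext
        if theta != 1.0:
            rhs -= (1.0 - theta) * (g_tot * v + lap @ v)
        mat = theta_lap.copy()
        mat[diag, diag] += cm_dt + theta * g_tot

        # refractory integrate-and-fire compartments are held at reset
        active_clamps: list[tuple[int, float]] = []
        for comp, clamp in clamps:
            active_clamps.append((comp, clamp.level_at(t_new)))
        for mech, idx, _ in iaf_rt:
            for cidx in idx:
                if refr_until[cidx] > t:
                    active_clamps.append((int(cidx), mech.reset))
        for comp, level in active_clamps:
            mat[comp, :] = identity_rows[comp]
            rhs[comp] = level

        v_new = np.linalg.solve(mat, rhs)
        if np.max(np.abs(v_new)) > V_LIMIT:
            raise DivergenceError(
                f"voltage exceeded {V_LIMIT} mV at t={t_new:.3f} ms; "
                f"dt={dt} ms is too coarse for this model")

        # clamp currents: residual of the unclamped balance at the node
        clamp_i = None
        if clamps:
            clamp_i = np.empty(len(clamps))
            memb = g_tot * v_new - (g_e + ge_syn)
            axial = lap @ v_new
            for k, (comp, _) in enumerate(clamps):
                clamp_i[k] = (cm_dt[comp] * (v_new[comp] - v[comp])
                              + memb[comp] + axial[comp] - i_ext[comp])

        # gate updates (exact exponential toward steady state at V^{n+1})
        for entry in chan_rt:
            channel, idx, g_abs, state = entry
            kind, data = state
            if kind == "gates":
                v_here = v_new[idx]
                for g_i, m in enumerate(data):
                    alpha, beta = gate_rates(entry, g_i, v_here, idx)
                    total = alpha + beta
                    inf = alpha / total
                    m_new = inf + (m - inf) * np.exp(-dt * total)
                    np.minimum(m_new, 1.0, out=m_new)
                    np.maximum(m_new, 0.0, out=m_new)
                    data[g_i] = m_new
            elif kind == "scheme":
                for row in range(len(idx)):
                    occ = ch.scheme_step(
                        channel.scheme, data[row], float(v_new[idx[row]]),
                        dt, ca=float(ca_conc[idx[row]]), temp=temp,
                        q10=channel.q10)
                    data[row] = occ

        # calcium pools (exact first-order update; influx = inward current)
        for pool, idx, conc in pools_rt:
            influx = -ica_out[idx]
            c_inf = (pool.resting_concentration
                     + pool.influx_scaling * pool.decay_time_constant
                     * influx)
            conc[:] = c_inf + (conc - c_inf) * math.exp(
                -dt / pool.decay_time_constant)
            np.clip(conc, 0.0, None, out=conc)
            ca_conc[idx] = conc

        # integrate-and-fire thresholding
        for mech, idx, _ in iaf_rt:
            for cidx in idx:
                cidx = int(cidx)
                if refr_until[cidx] > t:
                    v_new[cidx] = mech.reset
                    continue
                if v_new[cidx] >= mech.threshold:
                    iaf_spikes.setdefault(cidx, []).append(t_new)
                    v_new[cidx] = mech.reset
                    refr_until[cidx] = t_new + mech.refractory
                    for pre, site, delay, weight in proj_rt:
                        if pre == cidx:
                            site.add_event(t_new + delay, weight)

        # projection spike propagation from non-IaF (HH) cells
        if proj_rt:
            above = v_new >= config.spike_threshold
            crossed = above & ~prev_above & ~iaf_comp_mask
            if np.any(crossed):
                for pre, site, delay, weight in proj_rt:
                    if crossed[pre]:
                        site.add_event(t_new + delay, weight)
            prev_above = above

        v = v_new
        t = t_new
        snapshot(step, v, clamp_i)

    # --- package results -----------------------------------------------------
    recordings: dict[str, Recording] = {}
    spike_trains: dict[str, SpikeTrain] = {}
    for k, (label, comp) in enumerate(rec_comps):
        recordings[f"v:{label}"] = Recording("voltage", label, dt,
                                             v_store[:, k].copy())
        if iaf_comp_mask[comp]:
            spike_trains[label] = SpikeTrain(
                times=np.array(iaf_spikes.get(comp, [])))
        else:
            spike_trains[label] = detect_spikes(
                v_store[:, k], dt, config.spike_threshold)
    for k, (comp, clamp) in enumerate(clamps):
        recordings[f"clamp_current:{k}"] = Recording(
            "clamp current", str(clamp.target), dt, clamp_store[:, k].copy())
    if ca_store is not None:
        for k, (pool, idx, _) in enumerate(pools_rt):
            recordings[f"ca:{pool.id}"] = Recording(
                "concentration", pool.id, dt, ca_store[:, k].copy())
    return RunResult(dt=dt, duration=duration, recordings=recordings,
                     spike_trains=spike_trains)


def _cell_index(graph: CompartmentGraph, population_or_cell: str,
                offset: int = 0) -> int:
    """Map (population cell type, index-within-population) onto the graph's
    cell slots.  Cells are registered in population order by network runs;
    the cell id recorded in the graph is '<population>[<i>]' in that case,
    or the plain cell id for single/multi-cell runs."""
    label = f"{population_or_cell}[{offset}]"
    for k, (cid, *_rest) in enumerate(graph.cells):
        if cid == label:
            return k
    for k, (cid, *_rest) in enumerate(graph.cells):
        if cid == population_or_cell and offset == 0:
            return k
    raise SimulationError(f"no cell {label!r} in graph")


def simulate_network(document, duration: float, config: SolverConfig,
                     ) -> RunResult:
    """Instantiate and run a Level 3 document's network end to end.

    Each population instance becomes one cell in the compartment graph
    (labelled ``<population>[<index>]``); network inputs are mapped to
    per-cell stimuli, with random amplitudes/event times drawn from
    streams keyed by ``(config.seed, input name, cell)``.
    """
    import dataclasses

    from .network import instantiate as net_instantiate
    net = document.network
    if net is None:
        raise SimulationError("document has no network")
    if hasattr(net, "seed"):
        net = net_instantiate(net, config.seed)
    cell_types = document.cell_index()
    mechanisms = document.mechanism_index()

    cells: list[BiophysicalCell] = []
    slot: dict[tuple[str, int], int] = {}
    for pop in net.populations:
        proto = cell_types[pop.cell_type]
        if not isinstance(proto, BiophysicalCell):
            raise SimulationError(
                f"population {pop.name!r}: cell type {pop.cell_type!r} "
                f"has no biophysics")
        for inst in pop.instances:
            label = f"{pop.name}[{inst.index}]"
            morph = dataclasses.replace(proto.morphology, id=label)
            cells.append(dataclasses.replace(proto, morphology=morph))
            slot[(pop.name, inst.index)] = len(cells) - 1

    graph = build_graph(cells, config, mechanisms)
    stimuli: list[Stimulus] = []
    for inp in net.inputs:
        pop = net.population(inp.target_population)
        targets = (inp.cells if inp.cells is not None
                   else [i.index for i in pop.instances])
        for cidx in targets:
            target = (slot[(pop.name, cidx)], inp.segment, inp.fraction)
            if inp.kind == "current-pulse":
                stimuli.append(CurrentPulse(
                    target=target, amplitude=inp.amplitude,
                    delay=inp.delay, duration=inp.duration))
            elif inp.kind == "continuous-random-current":
                stimuli.append(RandomCurrent(
                    target=target, amplitude_min=inp.amplitude_min,
                    amplitude_max=inp.amplitude_max,
                    name=f"{inp.name}:{pop.name}[{cidx}]"))
            else:
                stimuli.append(SynapticEvents(
                    target=target, synapse_id=inp.synapse_id,
                    rate=inp.rate,
                    name=f"{inp.name}:{pop.name}[{cidx}]"))
    return run(graph, mechanisms, stimuli, duration, config,
               projections=net.projections)


def run_voltage_clamp(graph: CompartmentGraph, mechanisms: dict[str, object],
                      target: Target, holding_levels: Sequence[tuple[float, float]],
                      synaptic_events: Sequence[SynapticEvents],
                      duration: float, config: SolverConfig) -> Recording:
    """Voltage-clamp protocol: pin ``target`` to a level schedule, deliver
    synaptic events, return the clamp-current recording (nA)."""
    stimuli: list[Stimulus] = [VoltageClamp(target, holding_levels)]
    stimuli.extend(synaptic_events)
    result = run(graph, mechanisms, stimuli, duration, config)
    return result.recordings["clamp_current:0"]
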