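"""Self-validating NeuroML fixture documents plus companion protocols.

Every fixture is generated in memory (no downloads), validates cleanly,
and comes bundled with the stimulus/solver configuration of the protocol
it emulates:

* ``hh-point-cell`` -- spherical soma with classic squid Hodgkin-Huxley
  Na+/K+/leak kinetics and a suprathreshold current step.
* ``ball-and-stick`` -- the same kinetics on a soma plus a 100 um
  five-segment dendrite; the workhorse for spatial-discretisation and
  symmetric-vs-asymmetric solver convergence studies.
* ``passive-pair-gap-junction`` -- two passive cells coupled by a 300 pS
  electrical synapse, 0.19 nA step into one of them.
* ``ampa-nmda-clamp-cell`` -- a passive compartment (leak 3.0e-9
  mS/um^2 = 0.3 mS/cm^2, capacitance 1e-8 uF/um^2 = 1 uF/cm^2) receiving
  AMPA-only or NMDA-only input under voltage clamp at -80 and -20 mV.
* ``stp-pair`` -- a spontaneously active integrate-and-fire cell driving
  three passive targets through control / depressing (tau_rec = 120 ms) /
  facilitating (tau_fac = 300 ms) short-term-plasticity synapses.
* ``reduced-L23-network`` -- a 56-cell, five-population cortical layer
  2/3 skeleton (20 regular-spiking + 6 fast-rhythmic-bursting pyramidal
  cells, 10 low-threshold-spiking, 10 axo-axonic and 10 basket
  interneurons) placed at random in a cylinder, with electrical coupling
  inside each population (2.1 nS = 0.7 x 3 nS), chemical projections
  between them, and random current drive.  Cell dynamics are placeholder
  integrate-and-fire point neurons: the full conductance complement of
  the original cortical model lives in external model files and is out
  of scope here.

The HH parameters are the classic squid-axon values (gNa 120, gK 36,
leak 0.3 mS/cm^2; ENa +50, EK -77, Eleak -54.3 mV), labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import channels as ch
from . import synapses as syn
from .io import NeuroMLDocument
from .meta import Metadata
from .morphology import (BiophysicalCell, Cable, CellMorphology,
                         ChannelPlacement, Point3D, Segment)
from .network import (CellInstance, Connection, Cylinder, FixedProbability,
                      NetworkInput, NetworkTemplate, Population,
                      PopulationTemplate, Projection, attach_gap_junctions,
                      instantiate)
from .simulator import (CurrentPulse, SolverConfig, Stimulus, SynapticEvents,
                        VoltageClamp)
from .units import UnitSystem

FIXTURE_NAMES = ("hh-point-cell", "ball-and-stick",
                 "passive-pair-gap-junction", "ampa-nmda-clamp-cell",
                 "stp-pair", "reduced-L23-network")


@dataclass
class FixtureBundle:
    """A generated document plus the protocol that exercises it."""

    name: str
    document: NeuroMLDocument
    stimuli: list[Stimulus] = field(default_factory=list)
    config: SolverConfig = field(default_factory=SolverConfig)
    duration: float = 100.0    # ms
    notes: str = ""


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def squid_hh_channels() -> list[ch.ChannelType]:
    """Classic squid-axon Hodgkin-Huxley Na+, K+ and leak conductances
    (rest shifted to -65 mV)."""
    na = ch.ChannelType(
        id="na_hh", max_conductance_density=120.0, reversal_potential=50.0,
        ion="na",
        gates=[
            ch.Gate("m", instances=3,
                    forward=ch.RateLaw("exp_linear", rate=1.0, scale=0.1,
                                       midpoint=-40.0),
                    backward=ch.RateLaw("exponential", rate=4.0,
                                        scale=-1.0 / 18.0, midpoint=-65.0)),
            ch.Gate("h", instances=1,
                    forward=ch.RateLaw("exponential", rate=0.07,
                                       scale=-0.05, midpoint=-65.0),
                    backward=ch.RateLaw("sigmoid", rate=1.0, scale=-0.1,
                                        midpoint=-35.0)),
        ])
    k = ch.ChannelType(
        id="k_hh", max_conductance_density=36.0, reversal_potential=-77.0,
        ion="k",
        gates=[
            ch.Gate("n", instances=4,
                    forward=ch.RateLaw("exp_linear", rate=0.1, scale=0.1,
                                       midpoint=-55.0),
                    backward=ch.RateLaw("exponential", rate=0.125,
                                        scale=-1.0 / 80.0, midpoint=-65.0)),
        ])
    leak = ch.ChannelType(
        id="leak_hh", max_conductance_density=0.3,
        reversal_potential=-54.3, passive=True)
    return [na, k, leak]


def sphere_morphology(cell_id: str, diameter: float,
                      groups: set[str] | None = None) -> CellMorphology:
    p = Point3D(0.0, 0.0, 0.0, diameter)
    return CellMorphology(
        id=cell_id,
        segments=[Segment(id="0", proximal=p, distal=p, cable="0",
                          name="soma")],
        cables=[Cable(id="0", name="soma", segment_ids=["0"],
                      groups=(groups or set()) | {"soma_group"})])


def ball_and_stick_morphology(cell_id: str = "ball_and_stick",
                              soma_diameter: float = 20.0,
                              n_dendrite_segments: int = 5,
                              segment_length: float = 20.0,
                              dendrite_diameter: float = 2.0,
                              dendrite_divisions: int = 40,
                              ) -> CellMorphology:
    """Spherical soma plus a straight dendrite of equal-length segments."""
    soma_p = Point3D(0.0, 0.0, 0.0, soma_diameter)
    segments = [Segment(id="0", proximal=soma_p, distal=soma_p, cable="0",
                        name="soma")]
    dend_ids = []
    for i in range(n_dendrite_segments):
        sid = str(i + 1)
        segments.append(Segment(
            id=sid,
            proximal=(Point3D(0.0, 0.0, 0.0, dendrite_diameter)
                      if i == 0 else None),
            distal=Point3D((i + 1) * segment_length, 0.0, 0.0,
                           dendrite_diameter),
            parent=str(i), cable="1",
            name=f"dend_{i}"))
        dend_ids.append(sid)
    return CellMorphology(
        id=cell_id,
        segments=segments,
        cables=[
            Cable(id="0", name="soma", segment_ids=["0"],
                  groups={"soma_group"}),
            Cable(id="1", name="dendrite", segment_ids=dend_ids,
                  groups={"dendrite_group"},
                  internal_divisions=dendrite_divisions)])


def passive_cell(cell_id: str, diameter: float = 50.0,
                 leak_density: float = 0.3, leak_reversal: float = -65.0,
                 capacitance: float = 1.0) -> tuple[BiophysicalCell,
                                                    ch.ChannelType]:
    leak = ch.ChannelType(id=f"{cell_id}_leak",
                          max_conductance_density=leak_density,
                          reversal_potential=leak_reversal, passive=True)
    cell = BiophysicalCell(
        morphology=sphere_morphology(cell_id, diameter),
        specific_capacitance={"all": capacitance},
        mechanism_placements=[
            ChannelPlacement(leak.id, leak_density, {"all"})])
    return cell, leak


# ---------------------------------------------------------------------------
# the fixtures
# ---------------------------------------------------------------------------

def _hh_point_cell(seed: int, **overrides) -> FixtureBundle:
    amplitude = overrides.get("amplitude", 0.2)    # nA
    dt = overrides.get("dt", 0.005)
    chans = squid_hh_channels()
    cell = BiophysicalCell(
        morphology=sphere_morphology("hh_point_cell", 20.0),
        mechanism_placements=[
            ChannelPlacement(c.id,
                             c.max_conductance_density, {"all"})
            for c in chans])
    doc = NeuroMLDocument(
        level=2, unit_system=UnitSystem.PHYSIOLOGICAL,
        metadata=Metadata(comments="Single-compartment cell with classic "
                                   "squid Hodgkin-Huxley kinetics"),
        cells=[cell], channels=chans)
    stim = CurrentPulse(target=(0, "0", 0.5), amplitude=amplitude,
                        delay=10.0, duration=1e9)
    return FixtureBundle(
        name="hh-point-cell", document=doc, stimuli=[stim],
        config=SolverConfig(dt=dt, temperature=6.3, seed=seed,
                            initial_voltage=-65.0),
        duration=overrides.get("duration", 100.0))


def _ball_and_stick(seed: int, **overrides) -> FixtureBundle:
    amplitude = overrides.get("amplitude", 0.3)
    dt = overrides.get("dt", 0.005)
    divisions = overrides.get("dendrite_divisions", 40)
    chans = squid_hh_channels()
    morph = ball_and_stick_morphology(dendrite_divisions=divisions)
    cell = BiophysicalCell(
        morphology=morph,
        mechanism_placements=[
            ChannelPlacement(c.id, c.max_conductance_density, {"all"})
            for c in chans])
    doc = NeuroMLDocument(
        level=2,
        metadata=Metadata(comments="Ball-and-stick cell with uniform "
                                   "squid Hodgkin-Huxley kinetics"),
        cells=[cell], channels=chans)
    stim = CurrentPulse(target=(0, "0", 0.5), amplitude=amplitude,
                        delay=5.0, duration=1e9)
    return FixtureBundle(
        name="ball-and-stick", document=doc, stimuli=[stim],
        config=SolverConfig(dt=dt, temperature=6.3, seed=seed),
        duration=overrides.get("duration", 200.0))


def _passive_pair_gap_junction(seed: int, **overrides) -> FixtureBundle:
    g_gap = overrides.get("gap_conductance", 300e-6)   # 300 pS in uS
    amplitude = overrides.get("amplitude", 0.19)       # nA
    cell, leak = passive_cell("passive_cell")
    gj = syn.GapJunction(id="gap_300pS", conductance=g_gap)
    net = NetworkTemplate(
        populations=[Population(
            name="pair", cell_type="passive_cell",
            instances=[CellInstance(0, 0.0, 0.0, 0.0),
                       CellInstance(1, 100.0, 0.0, 0.0)])],
        projections=[Projection(
            name="coupling", source="pair", target="pair",
            synapse_id="gap_300pS", electrical=True,
            connections=[Connection(pre_cell=0, post_cell=1)])],
        inputs=[NetworkInput(
            name="step", kind="current-pulse", target_population="pair",
            amplitude=amplitude, delay=20.0, duration=100.0, cells=[0])],
        seed=seed)
    doc = NeuroMLDocument(
        level=3,
        metadata=Metadata(comments="Pair of passive cells coupled by a "
                                   "300 pS gap junction"),
        cells=[cell], channels=[leak], synapses=[gj], network=net)
    return FixtureBundle(
        name="passive-pair-gap-junction", document=doc,
        config=SolverConfig(dt=overrides.get("dt", 0.01), seed=seed),
        duration=overrides.get("duration", 160.0))


def default_ampa() -> syn.DoubleExpSynapse:
    return syn.DoubleExpSynapse(id="AMPA", max_conductance=1e-3,
                                reversal=0.0, rise_time=0.2,
                                decay_times=(2.0,))


def default_nmda() -> syn.BlockingSynapse:
    """NMDA-style blocked synapse; block parameters are package fixture
    conventions (1 mM Mg2+, eta 0.28 mM^-1, gamma 0.062 mV^-1)."""
    base = syn.DoubleExpSynapse(id="NMDA", max_conductance=1e-3,
                                reversal=0.0, rise_time=1.0,
                                decay_times=(80.0,))
    return syn.BlockingSynapse(
        base=base, block=syn.MgBlock(mg_concentration=1.0, eta=0.28,
                                     gamma=0.062))


def _ampa_nmda_clamp_cell(seed: int, **overrides) -> FixtureBundle:
    # Methods-style passive compartment: 3.0e-9 mS/um^2 and 1e-8 uF/um^2
    cell, leak = passive_cell("clamp_cell", diameter=20.0,
                              leak_density=0.3, capacitance=1.0)
    ampa, nmda = default_ampa(), default_nmda()
    doc = NeuroMLDocument(
        level=2,
        metadata=Metadata(comments="Passive compartment for AMPA/NMDA "
                                   "voltage-clamp EPSC protocols"),
        cells=[cell], channels=[leak], synapses=[ampa, nmda])
    holding = overrides.get("holding", -80.0)
    stimuli: list[Stimulus] = [
        VoltageClamp(target=(0, "0", 0.5), levels=[(0.0, holding)]),
        SynapticEvents(target=(0, "0", 0.5),
                       synapse_id=overrides.get("synapse", "AMPA"),
                       times=[20.0])]
    return FixtureBundle(
        name="ampa-nmda-clamp-cell", document=doc, stimuli=stimuli,
        config=SolverConfig(dt=overrides.get("dt", 0.01), seed=seed),
        duration=overrides.get("duration", 120.0))


def stp_synapse(mode: str, base: syn.DoubleExpSynapse | None = None,
                ) -> syn.STPSynapse:
    """The three short-term-plasticity protocol configurations:
    ``control`` (both time constants 0: plasticity off), ``depressing``
    (tau_rec = 120 ms, tau_fac = 0) and ``facilitating`` (tau_rec = 0,
    tau_fac = 300 ms)."""
    if base is None:
        base = syn.DoubleExpSynapse(id=f"stp_{mode}", max_conductance=2e-3,
                                    reversal=0.0, rise_time=0.0,
                                    decay_times=(3.0,))
    if mode == "control":
        return syn.STPSynapse(base=base, utilisation=0.5, tau_rec=0.0,
                              tau_fac=0.0)
    if mode == "depressing":
        return syn.STPSynapse(base=base, utilisation=0.5, tau_rec=120.0,
                              tau_fac=0.0)
    if mode == "facilitating":
        return syn.STPSynapse(base=base, utilisation=0.1, tau_rec=0.0,
                              tau_fac=300.0)
    raise FixtureError(f"unknown STP mode {mode!r}")


def _stp_pair(seed: int, **overrides) -> FixtureBundle:
    mode = overrides.get("mode")
    # spontaneously active pre cell: leak reversal just above threshold
    pre_iaf = ch.IaFMechanism(id="pre_iaf", threshold=-50.0, reset=-70.0,
                              refractory=15.0, leak_conductance=0.3,
                              leak_reversal=-48.0)
    pre = BiophysicalCell(
        morphology=sphere_morphology("pre_cell", 30.0),
        mechanism_placements=[ChannelPlacement("pre_iaf", 0.3, {"all"})])
    post, post_leak = passive_cell("post_cell", diameter=30.0)
    modes = [mode] if mode else ["control", "depressing", "facilitating"]
    synapses = [stp_synapse(m) for m in modes]
    projections = [
        Projection(name=f"stp_{m}", source="pre", target="post",
                   synapse_id=f"stp_{m}",
                   connections=[Connection(pre_cell=0, post_cell=k)])
        for k, m in enumerate(modes)]
    net = NetworkTemplate(
        populations=[
            Population(name="pre", cell_type="pre_cell",
                       instances=[CellInstance(0, 0.0, 0.0, 0.0)]),
            Population(name="post", cell_type="post_cell",
                       instances=[CellInstance(k, 50.0 * (k + 1), 0.0, 0.0)
                                  for k in range(len(modes))])],
        projections=projections, seed=seed)
    doc = NeuroMLDocument(
        level=3,
        metadata=Metadata(comments="Spontaneously active pre cell driving "
                                   "targets through STP synapses"),
        cells=[pre, post], channels=[pre_iaf, post_leak],
        synapses=synapses, network=net)
    return FixtureBundle(
        name="stp-pair", document=doc,
        config=SolverConfig(dt=overrides.get("dt", 0.025), seed=seed),
        duration=overrides.get("duration", 400.0))


#: layer 2/3 population sizes: RS and FRB pyramidal cells, LTS,
#: axo-axonic and basket interneurons
L23_POPULATIONS = (("RS", 20), ("FRB", 6), ("LTS", 10),
                   ("axoaxonic", 10), ("basket", 10))
#: gap junction conductance: base 3 nS scaled by 0.7 -> 2.1 nS (in uS)
L23_GAP_CONDUCTANCE = 2.1e-3


def _reduced_l23_network(seed: int, **overrides) -> FixtureBundle:
    region = Cylinder(x=0.0, y=0.0, z=0.0, radius=300.0, height=200.0)
    iaf = ch.IaFMechanism(id="point_iaf", threshold=-50.0, reset=-70.0,
                          refractory=3.0, leak_conductance=0.3,
                          leak_reversal=-65.0)
    cell = BiophysicalCell(
        morphology=sphere_morphology("point_cell", 30.0),
        mechanism_placements=[ChannelPlacement("point_iaf", 0.3, {"all"})])
    ampa = default_ampa()
    gaba = syn.DoubleExpSynapse(id="GABA", max_conductance=1e-3,
                                reversal=-75.0, rise_time=0.5,
                                decay_times=(6.0,))
    gj = syn.GapJunction(id="gap_2.1nS", conductance=L23_GAP_CONDUCTANCE)

    populations = [
        Population(name=name, cell_type="point_cell",
                   template=PopulationTemplate(count=count, region=region))
        for name, count in L23_POPULATIONS]
    template = NetworkTemplate(populations=populations, seed=seed)
    instance = instantiate(template, seed)

    # electrical connections within each population
    for pop in instance.populations:
        instance.projections.append(attach_gap_junctions(
            pop, FixedProbability(0.15), "gap_2.1nS",
            L23_GAP_CONDUCTANCE, seed))
    # representative chemical projections between populations
    chem = [("RS", "FRB", "AMPA", 0.1), ("FRB", "RS", "AMPA", 0.1),
            ("RS", "LTS", "AMPA", 0.1), ("LTS", "RS", "GABA", 0.15),
            ("basket", "RS", "GABA", 0.15),
            ("axoaxonic", "RS", "GABA", 0.1)]
    for src, tgt, sid, p in chem:
        instance.projections.append(connect_pops(instance, src, tgt, sid,
                                                 p, seed))
    instance.inputs.extend([
        NetworkInput(name="frb_drive", kind="continuous-random-current",
                     target_population="FRB", amplitude_min=0.15,
                     amplitude_max=0.25),
        NetworkInput(name="lts_drive", kind="continuous-random-current",
                     target_population="LTS", amplitude_min=0.0,
                     amplitude_max=0.2),
        NetworkInput(name="basket_drive", kind="continuous-random-current",
                     target_population="basket", amplitude_min=0.0,
                     amplitude_max=0.02),
        NetworkInput(name="axoaxonic_drive",
                     kind="continuous-random-current",
                     target_population="axoaxonic", amplitude_min=0.0,
                     amplitude_max=0.02),
        NetworkInput(name="rs_noise", kind="random-synaptic-events",
                     target_population="RS", rate=1.0, synapse_id="AMPA")])
    doc = NeuroMLDocument(
        level=3,
        metadata=Metadata(comments="Reduced 56-cell five-population layer "
                                   "2/3 network skeleton with placeholder "
                                   "integrate-and-fire dynamics"),
        cells=[cell], channels=[iaf],
        synapses=[ampa, gaba, gj], network=instance)
    return FixtureBundle(
        name="reduced-L23-network", document=doc,
        config=SolverConfig(dt=overrides.get("dt", 0.025), seed=seed),
        duration=overrides.get("duration", 250.0))


def connect_pops(net, src: str, tgt: str, synapse_id: str, p: float,
                 seed: int) -> Projection:
    from .network import connect
    return connect(net.population(src), net.population(tgt),
                   FixedProbability(p), synapse_id, seed,
                   name=f"{src}_to_{tgt}_{synapse_id}")


_BUILDERS = {
    "hh-point-cell": _hh_point_cell,
    "ball-and-stick": _ball_and_stick,
    "passive-pair-gap-junction": _passive_pair_gap_junction,
    "ampa-nmda-clamp-cell": _ampa_nmda_clamp_cell,
    "stp-pair": _stp_pair,
    "reduced-L23-network": _reduced_l23_network,
}


def generate_fixture(name: str, seed: int = 0, **overrides) -> FixtureBundle:
    """Generate a named fixture; deterministic given ``seed``."""
    if name not in _BUILDERS:
        raise FixtureError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return _BUILDERS[name](seed, **overrides)


def synthetic_large_morphology(n_cables: int = 173,
                               n_segments: int = 2243) -> CellMorphology:
    """SYNTHETIC stand-in morphology with a prescribed cable/segment count.

    Shaped like a large reconstructed pyramidal cell export (one soma
    cable plus branching dendritic cables whose segment counts sum to the
    requested total), but generated procedurally -- it carries no real
    reconstruction data and is used only to exercise parser and
    serializer at realistic document sizes.
    """
    soma_p = Point3D(0.0, 0.0, 0.0, 20.0)
    segments = [Segment(id="0", proximal=soma_p, distal=soma_p, cable="0")]
    cables = [Cable(id="0", name="soma", segment_ids=["0"],
                    groups={"soma_group"})]
    remaining = n_segments - 1
    attach = ["0"]   # segment ids available as branch points
    next_id = 1
    for c in range(1, n_cables):
        cables_left = n_cables - c
        take = max(1, math.ceil(remaining / cables_left))
        parent = attach[(c * 7) % len(attach)]
        seg_ids = []
        for k in range(take):
            sid = str(next_id)
            angle = 0.618 * next_id
            base = segments[int(parent)].distal if k == 0 else \
                segments[-1].distal
            segments.append(Segment(
                id=sid,
                proximal=(Point3D(base.x, base.y, base.z, 1.5)
                          if k == 0 else None),
                distal=Point3D(base.x + 5.0 * math.cos(angle),
                               base.y + 5.0 * math.sin(angle),
                               base.z + 1.0, 1.5),
                parent=parent if k == 0 else str(next_id - 1),
                cable=str(c)))
            parent = sid
            seg_ids.append(sid)
            next_id += 1
        remaining -= take
        attach.append(seg_ids[-1])
        cables.append(Cable(id=str(c), name=f"dend_{c}",
                            segment_ids=seg_ids,
                            groups={"dendrite_group"}))
    return CellMorphology(id="synthetic_large", segments=segments,
                          cables=cables)
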