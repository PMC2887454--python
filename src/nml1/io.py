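"""NeuroML v1.x document model, parsing, validation and serialization.

The document is the unit of exchange: a Level 1 file carries morphologies
and metadata, Level 2 adds biophysics and membrane mechanisms
(ChannelML), Level 3 adds networks (NetworkML); a Level N file may
contain any element legal at Level <= N.  Exactly one unit system (SI or
Physiological) applies to the whole file; in-memory objects always store
Physiological magnitudes, so conversion happens here and only here.

Unknown elements are collected -- with a warning -- rather than rejected,
and re-emitted verbatim on serialization, so annotations and proprietary
extensions survive a round trip.  A bundled XSD checks the structural
envelope of the dialect; the Python validator enforces the semantic
invariants (reference resolution, invariant ranges, level legality) and
reports findings in document order.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
from lxml import etree

from . import channels as ch
from . import synapses as syn
from .meta import Metadata, Person
from .morphology import (BiophysicalCell, Cable, CellMorphology,
                         ChannelPlacement, IonPoolPlacement, Point3D, Segment,
                         VariableParameter, check_integrity)
from .network import (Box, CellInstance, Connection, Cylinder,
                      NetworkInput, NetworkInstance, NetworkTemplate,
                      Population, PopulationTemplate, Projection)
from .units import Dimension, UnitSystem, convert

NAMESPACE = "http://morphml.org/neuroml/schema"
SCHEMA_VERSION = "1.8.1"
_NS = f"{{{NAMESPACE}}}"

#: extra conversion factors (SI -> Physiological) for compound dimensions
#: used only at the XML boundary
_EXTRA_SI_TO_PHYS = {
    "inverse-time": 1e-3,          # s^-1 -> ms^-1
    "inverse-voltage": 1e-3,       # V^-1 -> mV^-1
    "inverse-concentration": 1.0,  # (mol/m^3)^-1 == mM^-1
    "ca-influx": 1e-12,            # (mol/m^3)/(A s) -> mM/(nA ms)
}


class NMLError(ValueError):
    pass


class NMLParseError(NMLError):
    pass


class NMLReferenceError(NMLError):
    """A referenced identifier does not resolve within the document."""


class NMLValidationError(NMLError):
    """Raised when serialization is refused; carries the report."""

    def __init__(self, report: "ValidationReport"):
        super().__init__("document failed validation:\n" + report.pretty())
        self.report = report


# ---------------------------------------------------------------------------
# document model
# ---------------------------------------------------------------------------

CellLike = Union[CellMorphology, BiophysicalCell]
MechanismLike = Union[ch.ChannelType, ch.IaFMechanism]


@dataclass
class NeuroMLDocument:
    level: int = 1
    unit_system: UnitSystem = UnitSystem.PHYSIOLOGICAL
    metadata: Metadata = field(default_factory=Metadata)
    cells: list[CellLike] = field(default_factory=list)
    channels: list[MechanismLike] = field(default_factory=list)
    synapses: list[syn.SynapseType] = field(default_factory=list)
    ion_pools: list[ch.IonConcentrationModel] = field(default_factory=list)
    network: Optional[NetworkInstance] = None
    warnings: list[str] = field(default_factory=list)
    #: unknown elements preserved opaquely: (parent path, XML bytes)
    foreign: list[tuple[str, bytes]] = field(default_factory=list)

    def mechanism_index(self) -> dict[str, object]:
        """id -> mechanism object, across channels, pools and synapses."""
        out: dict[str, object] = {}
        for mech in self.channels:
            out[mech.id] = mech
        for pool in self.ion_pools:
            out[pool.id] = pool
        for s in self.synapses:
            out[s.id] = s
        return out

    def cell_index(self) -> dict[str, CellLike]:
        return {c.id: c for c in self.cells}


def structurally_equal(a: NeuroMLDocument, b: NeuroMLDocument) -> bool:
    """Structural equality ignoring warnings (foreign payloads compared
    byte-for-byte)."""
    return (a.level == b.level and a.unit_system == b.unit_system
            and a.metadata == b.metadata and a.cells == b.cells
            and a.channels == b.channels and a.synapses == b.synapses
            and a.ion_pools == b.ion_pools and a.network == b.network
            and [f[1] for f in a.foreign] == [f[1] for f in b.foreign])


# ---------------------------------------------------------------------------
# unit helpers
# ---------------------------------------------------------------------------

def _to_internal(value: float, dim, system: UnitSystem) -> float:
    """Convert a parsed magnitude to the internal Physiological system."""
    if system is UnitSystem.PHYSIOLOGICAL:
        return value
    if isinstance(dim, Dimension):
        return convert(value, dim, UnitSystem.SI, UnitSystem.PHYSIOLOGICAL)
    return value * _EXTRA_SI_TO_PHYS[dim]


def _from_internal(value: float, dim, system: UnitSystem) -> float:
    if system is UnitSystem.PHYSIOLOGICAL:
        return value
    if isinstance(dim, Dimension):
        return convert(value, dim, UnitSystem.PHYSIOLOGICAL, UnitSystem.SI)
    return value / _EXTRA_SI_TO_PHYS[dim]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _float(el: etree._Element, attr: str, default: Optional[float] = None,
           ) -> float:
    raw = el.get(attr)
    if raw is None:
        if default is None:
            raise NMLParseError(
                f"element <{_localname(el)}> (line {el.sourceline}) is "
                f"missing required attribute {attr!r}")
        return default
    try:
        return float(raw)
    except ValueError as exc:
        raise NMLParseError(
            f"attribute {attr}={raw!r} on <{_localname(el)}> is not a "
            f"number (line {el.sourceline})") from exc


class _Parser:
    def __init__(self, root: etree._Element):
        self.root = root
        self.doc = NeuroMLDocument()
        self.warnings = self.doc.warnings

    def _known(self, el: etree._Element, names: Iterable[str],
               path: str) -> list[etree._Element]:
        """Children with known tags; unknown ones preserved + warned."""
        known = []
        nameset = set(names)
        for child in el:
            if isinstance(child, etree._Comment):
                continue
            name = _localname(child)
            if name in nameset:
                known.append(child)
            else:
                self.warnings.append(
                    f"unknown element <{name}> under {path} preserved "
                    f"opaquely")
                self.doc.foreign.append(
                    (path, etree.tostring(child)))
        return known

    def q(self, el, attr, dim, default=None) -> float:
        return _to_internal(_float(el, attr, default), dim,
                            self.doc.unit_system)

    # -- top level ---------------------------------------------------------

    def parse(self) -> NeuroMLDocument:
        root = self.root
        if _localname(root) != "neuroml":
            raise NMLParseError(
                f"root element is <{_localname(root)}>, expected <neuroml>")
        units = root.get("units", UnitSystem.PHYSIOLOGICAL.value)
        self.doc.unit_system = UnitSystem.from_string(units)
        self.doc.level = int(root.get("level", "1"))
        self._check_uniform_units(root)
        containers = self._known(
            root, ["notes", "authors", "translators", "publications",
                   "database_refs", "status", "cells", "channels",
                   "synapses", "network"], "/neuroml")
        for el in containers:
            name = _localname(el)
            if name == "notes":
                self.doc.metadata.comments = el.text or ""
            elif name in ("authors", "translators"):
                people = [Person(p.get("name", ""), p.get("institution", ""))
                          for p in el if _localname(p) == "person"]
                setattr(self.doc.metadata, name, people)
            elif name == "publications":
                self.doc.metadata.publications = [
                    p.text or "" for p in el
                    if _localname(p) == "publication"]
            elif name == "database_refs":
                self.doc.metadata.database_refs = [
                    (r.get("database", ""), r.get("accession", ""))
                    for r in el if _localname(r) == "database_ref"]
            elif name == "status":
                self.doc.metadata.status = el.get("value", "")
                self.doc.metadata.status_comment = el.text or ""
            elif name == "cells":
                for cell_el in el:
                    if _localname(cell_el) == "cell":
                        self.doc.cells.append(self._cell(cell_el))
            elif name == "channels":
                self._channels(el)
            elif name == "synapses":
                for s_el in el:
                    if _localname(s_el) == "synapse_type":
                        self.doc.synapses.append(self._synapse(s_el))
            elif name == "network":
                self.doc.network = self._network(el)
        self._resolve_references()
        return self.doc

    def _check_uniform_units(self, root) -> None:
        declared = self.doc.unit_system
        for el in root.iter():
            if isinstance(el, etree._Comment):
                continue
            local = el.get("units")
            if local is None or _localname(el) == "neuroml":
                continue
            if UnitSystem.from_string(local) is not declared:
                raise NMLError(
                    f"mixed unit systems: <{_localname(el)}> (line "
                    f"{el.sourceline}) declares {local!r} but the document "
                    f"declares {declared.value!r}")

    # -- cells -------------------------------------------------------------

    def _point(self, el) -> Point3D:
        sys = self.doc.unit_system
        return Point3D(
            x=_to_internal(_float(el, "x"), Dimension.LENGTH, sys),
            y=_to_internal(_float(el, "y"), Dimension.LENGTH, sys),
            z=_to_internal(_float(el, "z"), Dimension.LENGTH, sys),
            diameter=_to_internal(_float(el, "diameter"),
                                  Dimension.LENGTH, sys))

    def _cell(self, el) -> CellLike:
        cid = el.get("id") or el.get("name") or "cell"
        path = f"/neuroml/cells/cell[{cid}]"
        morph = CellMorphology(id=cid)
        bio: Optional[BiophysicalCell] = None
        for part in self._known(
                el, ["segments", "cables", "biophysics", "connectivity",
                     "notes"], path):
            name = _localname(part)
            if name == "segments":
                for s_el in part:
                    if _localname(s_el) != "segment":
                        continue
                    prox = dist = None
                    for p_el in s_el:
                        if _localname(p_el) == "proximal":
                            prox = self._point(p_el)
                        elif _localname(p_el) == "distal":
                            dist = self._point(p_el)
                    if dist is None:
                        raise NMLParseError(
                            f"segment {s_el.get('id')!r} has no distal "
                            f"point (line {s_el.sourceline})")
                    morph.segments.append(Segment(
                        id=s_el.get("id", ""), distal=dist, proximal=prox,
                        parent=s_el.get("parent"),
                        cable=s_el.get("cable", ""),
                        name=s_el.get("name", "")))
            elif name == "cables":
                for c_el in part:
                    if _localname(c_el) != "cable":
                        continue
                    groups = {g.text.strip() for g in c_el
                              if _localname(g) == "group" and g.text}
                    morph.cables.append(Cable(
                        id=c_el.get("id", ""), name=c_el.get("name", ""),
                        segment_ids=[s for s in
                                     (c_el.get("segments") or "").split()
                                     if s],
                        groups=groups,
                        internal_divisions=int(
                            c_el.get("internal_divisions", "1"))))
            elif name == "notes":
                morph.metadata.comments = part.text or ""
            elif name == "biophysics":
                bio = self._biophysics(part, morph)
            elif name == "connectivity":
                if bio is None:
                    bio = BiophysicalCell(morphology=morph)
                for loc in part:
                    if _localname(loc) != "potential_syn_loc":
                        continue
                    sid = loc.get("synapse", "")
                    grp = loc.get("group", "all")
                    bio.connectivity.setdefault(sid, set()).add(grp)
        return bio if bio is not None else morph

    def _biophysics(self, el, morph: CellMorphology) -> BiophysicalCell:
        bio = BiophysicalCell(morphology=morph, specific_capacitance={},
                              axial_resistivity={})
        for part in el:
            name = _localname(part)
            if name == "specific_capacitance":
                for v_el in part:
                    if _localname(v_el) == "value":
                        bio.specific_capacitance[v_el.get("group", "all")] = \
                            self.q(v_el, "value",
                                   Dimension.SPECIFIC_CAPACITANCE)
            elif name == "axial_resistivity":
                for v_el in part:
                    if _localname(v_el) == "value":
                        bio.axial_resistivity[v_el.get("group", "all")] = \
                            self.q(v_el, "value", Dimension.RESISTIVITY)
            elif name == "mechanism":
                chan = part.get("channel", "")
                for d_el in part:
                    dname = _localname(d_el)
                    if dname == "density":
                        bio.mechanism_placements.append(ChannelPlacement(
                            channel_id=chan,
                            density=self.q(d_el, "value",
                                           Dimension.SPECIFIC_CONDUCTANCE),
                            groups={d_el.get("group", "all")}))
                    elif dname == "variable_density":
                        bio.mechanism_placements.append(ChannelPlacement(
                            channel_id=chan,
                            density=VariableParameter(
                                parameter_name="gmax",
                                metric=d_el.get(
                                    "metric", "path-distance-from-soma"),
                                expression=d_el.get("expression", "0"),
                                applies_to={d_el.get("group", "all")}),
                            groups={d_el.get("group", "all")}))
            elif name == "ion_pool":
                bio.ion_pool_placements.append(IonPoolPlacement(
                    pool_id=part.get("pool", ""),
                    groups={part.get("group", "all")}))
        if not bio.specific_capacitance:
            bio.specific_capacitance = {"all": 1.0}
        if not bio.axial_resistivity:
            bio.axial_resistivity = {"all": 0.1}
        return bio

    # -- channels ----------------------------------------------------------

    def _rate_law(self, el) -> ch.RateLaw:
        form = el.get("form", "exponential")
        if form == "generic":
            return ch.RateLaw(form="generic",
                              expression=el.get("expression", ""))
        scale = self.q(el, "scale", "inverse-voltage", default=0.0)
        return ch.RateLaw(
            form=form,
            rate=self.q(el, "rate", "inverse-time"),
            scale=scale,
            midpoint=self.q(el, "midpoint", Dimension.VOLTAGE, default=0.0))

    def _channels(self, el) -> None:
        for c_el in self._known(
                el, ["channel_type", "ion_concentration",
                     "integrate_and_fire"], "/neuroml/channels"):
            name = _localname(c_el)
            if name == "ion_concentration":
                self.doc.ion_pools.append(ch.IonConcentrationModel(
                    id=c_el.get("id", ""),
                    resting_concentration=self.q(
                        c_el, "resting", Dimension.CONCENTRATION),
                    decay_time_constant=self.q(c_el, "tau", Dimension.TIME),
                    influx_scaling=self.q(c_el, "phi", "ca-influx")))
                continue
            if name == "integrate_and_fire":
                self.doc.channels.append(ch.IaFMechanism(
                    id=c_el.get("id", ""),
                    threshold=self.q(c_el, "threshold", Dimension.VOLTAGE),
                    reset=self.q(c_el, "reset", Dimension.VOLTAGE),
                    refractory=self.q(c_el, "refractory", Dimension.TIME),
                    leak_conductance=self.q(
                        c_el, "leak_conductance",
                        Dimension.SPECIFIC_CONDUCTANCE),
                    leak_reversal=self.q(c_el, "leak_reversal",
                                         Dimension.VOLTAGE)))
                continue
            gates: list[ch.Gate] = []
            scheme = None
            q10 = None
            cid = c_el.get("id", "")
            for part in self._known(
                    c_el, ["gate", "kinetic_scheme", "q10", "notes"],
                    f"/neuroml/channels/channel_type[{cid}]"):
                pname = _localname(part)
                if pname == "q10":
                    q10 = ch.Q10Settings(
                        q10_factor=_float(part, "factor"),
                        experimental_temp=self.q(
                            part, "experimental_temp",
                            Dimension.TEMPERATURE))
                elif pname == "gate":
                    fwd = bwd = None
                    for r_el in part:
                        if _localname(r_el) == "forward":
                            fwd = self._rate_law(r_el)
                        elif _localname(r_el) == "backward":
                            bwd = self._rate_law(r_el)
                    if fwd is None or bwd is None:
                        raise NMLParseError(
                            f"gate {part.get('name')!r} in channel "
                            f"{cid!r} needs forward and backward rates")
                    gates.append(ch.Gate(
                        name=part.get("name", ""),
                        instances=int(part.get("instances", "1")),
                        forward=fwd, backward=bwd,
                        ligand_gated=part.get(
                            "ligand_gated", "false") == "true"))
                elif pname == "kinetic_scheme":
                    states = []
                    transitions = []
                    for s_el in part:
                        sname = _localname(s_el)
                        if sname == "state":
                            states.append(ch.SchemeState(
                                id=s_el.get("id", ""),
                                open=s_el.get("open", "false") == "true"))
                        elif sname == "transition":
                            transitions.append(ch.SchemeTransition(
                                from_state=s_el.get("from", ""),
                                to_state=s_el.get("to", ""),
                                rate=self._rate_law(s_el)))
                    scheme = ch.KineticScheme(states=states,
                                              transitions=transitions)
            self.doc.channels.append(ch.ChannelType(
                id=cid,
                max_conductance_density=self.q(
                    c_el, "default_gmax", Dimension.SPECIFIC_CONDUCTANCE),
                reversal_potential=self.q(c_el, "default_erev",
                                          Dimension.VOLTAGE),
                gates=gates, scheme=scheme, q10=q10,
                passive=c_el.get("passive", "false") == "true",
                ion=c_el.get("ion", "")))

    # -- synapses ----------------------------------------------------------

    def _double_exp(self, el, sid: str) -> syn.DoubleExpSynapse:
        taus, fracs = [], []
        for d_el in el:
            if _localname(d_el) == "decay":
                taus.append(self.q(d_el, "tau", Dimension.TIME))
                fracs.append(_float(d_el, "fraction", default=1.0))
        if not taus:
            taus = [self.q(el, "decay_time", Dimension.TIME)]
            fracs = [1.0]
        return syn.DoubleExpSynapse(
            id=sid,
            max_conductance=self.q(el, "max_conductance",
                                   Dimension.CONDUCTANCE),
            reversal=self.q(el, "reversal", Dimension.VOLTAGE),
            rise_time=self.q(el, "rise_time", Dimension.TIME, default=0.0),
            decay_times=tuple(taus), decay_fractions=tuple(fracs))

    def _synapse(self, el) -> syn.SynapseType:
        sid = el.get("id", "")
        for part in el:
            name = _localname(part)
            if name == "double_exp_syn":
                return self._double_exp(part, sid)
            if name == "blocking_syn":
                base = self._double_exp(part, sid)
                block = None
                for b_el in part:
                    if _localname(b_el) == "mg_block":
                        block = syn.MgBlock(
                            mg_concentration=self.q(
                                b_el, "concentration",
                                Dimension.CONCENTRATION),
                            eta=self.q(b_el, "eta",
                                       "inverse-concentration"),
                            gamma=self.q(b_el, "gamma", "inverse-voltage"))
                if block is None:
                    raise NMLParseError(
                        f"blocking synapse {sid!r} lacks <mg_block>")
                return syn.BlockingSynapse(base=base, block=block)
            if name == "stp_syn":
                base = None
                for b_el in part:
                    if _localname(b_el) == "double_exp_syn":
                        base = self._double_exp(b_el, sid)
                if base is None:
                    raise NMLParseError(
                        f"STP synapse {sid!r} lacks a base waveform")
                return syn.STPSynapse(
                    base=base,
                    utilisation=_float(part, "utilisation"),
                    tau_rec=self.q(part, "tau_rec", Dimension.TIME,
                                   default=0.0),
                    tau_fac=self.q(part, "tau_fac", Dimension.TIME,
                                   default=0.0))
            if name == "stdp_syn":
                return syn.STDPSynapse(
                    id=sid,
                    w_max=_float(part, "w_max"),
                    a_plus=_float(part, "a_plus"),
                    a_minus=_float(part, "a_minus"),
                    tau_plus=self.q(part, "tau_plus", Dimension.TIME),
                    tau_minus=self.q(part, "tau_minus", Dimension.TIME),
                    initial_weight=_float(part, "initial_weight",
                                          default=0.5))
            if name == "electrical_syn":
                return syn.GapJunction(
                    id=sid,
                    conductance=self.q(part, "conductance",
                                       Dimension.CONDUCTANCE))
        raise NMLParseError(f"synapse_type {sid!r} has no known body")

    # -- network -----------------------------------------------------------

    def _network(self, el):
        seed_attr = el.get("template_seed")
        net = (NetworkTemplate(seed=int(seed_attr))
               if seed_attr is not None else NetworkInstance())
        sys = self.doc.unit_system
        L = Dimension.LENGTH

        def length(e, attr, default=None):
            return _to_internal(_float(e, attr, default), L, sys)

        for section in self._known(
                el, ["populations", "projections", "inputs"],
                "/neuroml/network"):
            name = _localname(section)
            if name == "populations":
                for p_el in section:
                    if _localname(p_el) != "population":
                        continue
                    pop = Population(name=p_el.get("name", ""),
                                     cell_type=p_el.get("cell_type", ""))
                    for body in p_el:
                        bname = _localname(body)
                        if bname == "instances":
                            for i_el in body:
                                if _localname(i_el) != "instance":
                                    continue
                                loc = i_el.find(_NS + "location")
                                if loc is None:
                                    loc = i_el.find("location")
                                node = i_el.get("node_id")
                                pop.instances.append(CellInstance(
                                    index=int(i_el.get("id", "0")),
                                    x=length(loc, "x"), y=length(loc, "y"),
                                    z=length(loc, "z"),
                                    node_id=int(node)
                                    if node is not None else None))
                        elif bname == "template":
                            region = None
                            for r_el in body:
                                rname = _localname(r_el)
                                if rname == "box":
                                    region = Box(
                                        length(r_el, "x"), length(r_el, "y"),
                                        length(r_el, "z"),
                                        length(r_el, "width"),
                                        length(r_el, "height"),
                                        length(r_el, "depth"))
                                elif rname == "cylinder":
                                    region = Cylinder(
                                        length(r_el, "x"), length(r_el, "y"),
                                        length(r_el, "z"),
                                        length(r_el, "radius"),
                                        length(r_el, "height"))
                            pop.template = PopulationTemplate(
                                count=int(body.get("count", "0")),
                                region=region,
                                min_separation=length(
                                    body, "min_separation", 0.0))
                    net.populations.append(pop)
            elif name == "projections":
                for p_el in section:
                    if _localname(p_el) != "projection":
                        continue
                    cond = p_el.get("conductance")
                    proj = Projection(
                        name=p_el.get("name", ""),
                        source=p_el.get("source", ""),
                        target=p_el.get("target", ""),
                        synapse_id=p_el.get("synapse", ""),
                        electrical=p_el.get("electrical",
                                            "false") == "true",
                        conductance=_to_internal(
                            float(cond), Dimension.CONDUCTANCE, sys)
                        if cond is not None else None)
                    for c_el in p_el:
                        if _localname(c_el) != "connection":
                            continue
                        proj.connections.append(Connection(
                            pre_cell=int(c_el.get("pre_cell", "0")),
                            post_cell=int(c_el.get("post_cell", "0")),
                            pre_segment=c_el.get("pre_segment", "0"),
                            pre_fraction=_float(c_el, "pre_fraction",
                                                default=0.5),
                            post_segment=c_el.get("post_segment", "0"),
                            post_fraction=_float(c_el, "post_fraction",
                                                 default=0.5),
                            weight=_float(c_el, "weight", default=1.0),
                            delay=self.q(c_el, "delay", Dimension.TIME,
                                         default=0.0)))
                    net.projections.append(proj)
            elif name == "inputs":
                A = Dimension.CURRENT
                for i_el in section:
                    if _localname(i_el) != "input":
                        continue
                    cells_attr = i_el.get("cells")
                    net.inputs.append(NetworkInput(
                        name=i_el.get("name", ""),
                        kind=i_el.get("kind", "current-pulse"),
                        target_population=i_el.get("population", ""),
                        amplitude=self.q(i_el, "amplitude", A, default=0.0),
                        amplitude_min=self.q(i_el, "amplitude_min", A,
                                             default=0.0),
                        amplitude_max=self.q(i_el, "amplitude_max", A,
                                             default=0.0),
                        delay=self.q(i_el, "delay", Dimension.TIME,
                                     default=0.0),
                        duration=self.q(i_el, "duration", Dimension.TIME,
                                        default=0.0),
                        rate=_float(i_el, "rate", default=0.0),
                        synapse_id=i_el.get("synapse", ""),
                        segment=i_el.get("segment", "0"),
                        fraction=_float(i_el, "fraction", default=0.5),
                        cells=[int(c) for c in cells_attr.split()]
                        if cells_attr else None))
        return net

    # -- reference resolution ----------------------------------------------

    def _resolve_references(self) -> None:
        mech_ids = set(self.doc.mechanism_index())
        cell_ids = {c.id for c in self.doc.cells}
        for cell in self.doc.cells:
            if not isinstance(cell, BiophysicalCell):
                continue
            for pl in cell.mechanism_placements:
                if pl.channel_id not in mech_ids:
                    raise NMLReferenceError(
                        f"cell {cell.id!r} places unknown mechanism "
                        f"{pl.channel_id!r}")
            for pp in cell.ion_pool_placements:
                if pp.pool_id not in mech_ids:
                    raise NMLReferenceError(
                        f"cell {cell.id!r} places unknown ion pool "
                        f"{pp.pool_id!r}")
        net = self.doc.network
        if net is not None:
            pop_names = {p.name for p in net.populations}
            for pop in net.populations:
                if pop.cell_type not in cell_ids:
                    raise NMLReferenceError(
                        f"population {pop.name!r} uses unknown cell type "
                        f"{pop.cell_type!r}")
            for proj in net.projections:
                if proj.synapse_id not in mech_ids:
                    raise NMLReferenceError(
                        f"projection {proj.name!r} uses unknown synapse "
                        f"{proj.synapse_id!r}")
                for ref in (proj.source, proj.target):
                    if ref not in pop_names:
                        raise NMLReferenceError(
                            f"projection {proj.name!r} references unknown "
                            f"population {ref!r}")


def parse_document(source, expected_level: Optional[int] = None,
                   validate_schema: bool = True) -> NeuroMLDocument:
    """Parse a NeuroML document from XML text, bytes or a file path.

    All quantities are converted to the internal Physiological system and
    tagged with the document's declared unit system; unknown elements are
    collected into ``doc.warnings``/``doc.foreign``, not silently dropped.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode())
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise NMLParseError(f"malformed XML: {exc}") from exc
    doc = _Parser(root).parse()
    if validate_schema:
        for err in check_against_schema(root):
            doc.warnings.append(f"schema: {err}")
    if expected_level is not None and doc.level != expected_level:
        raise NMLParseError(
            f"document is Level {doc.level}, expected Level "
            f"{expected_level}")
    return doc


_SCHEMA_CACHE: Optional[etree.XMLSchema] = None


def check_against_schema(root: etree._Element) -> list[str]:
    """Validate the raw XML envelope against the bundled XSD."""
    global _SCHEMA_CACHE
    if _SCHEMA_CACHE is None:
        data = (importlib.resources.files("nml1") / "schema"
                / "neuroml1.xsd").read_bytes()
        _SCHEMA_CACHE = etree.XMLSchema(etree.fromstring(data))
    if _SCHEMA_CACHE.validate(root):
        return []
    return [f"line {e.line}: {e.message}" for e in _SCHEMA_CACHE.error_log]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


class _Writer:
    def __init__(self, doc: NeuroMLDocument, system: UnitSystem):
        self.doc = doc
        self.system = system

    def q(self, value: float, dim) -> str:
        return _fmt(_from_internal(value, dim, self.system))

    def write(self) -> etree._Element:
        doc = self.doc
        root = etree.Element(_NS + "neuroml", nsmap={None: NAMESPACE})
        root.set("units", self.system.value)
        root.set("level", str(doc.level))
        root.set("schema_version", SCHEMA_VERSION)
        self._metadata(root, doc.metadata)
        if doc.cells:
            cells = etree.SubElement(root, _NS + "cells")
            for cell in doc.cells:
                self._cell(cells, cell)
        if doc.channels or doc.ion_pools:
            channels = etree.SubElement(root, _NS + "channels")
            for mech in doc.channels:
                if isinstance(mech, ch.IaFMechanism):
                    self._iaf(channels, mech)
                else:
                    self._channel(channels, mech)
            for pool in doc.ion_pools:
                el = etree.SubElement(channels, _NS + "ion_concentration")
                el.set("id", pool.id)
                el.set("resting", self.q(pool.resting_concentration,
                                         Dimension.CONCENTRATION))
                el.set("tau", self.q(pool.decay_time_constant,
                                     Dimension.TIME))
                el.set("phi", self.q(pool.influx_scaling, "ca-influx"))
        if doc.synapses:
            synapses = etree.SubElement(root, _NS + "synapses")
            for s in doc.synapses:
                self._synapse(synapses, s)
        if doc.network is not None:
            self._network(root, doc.network)
        for parent_path, payload in doc.foreign:
            target = root
            if parent_path.endswith("]") and "/cell[" in parent_path:
                cid = parent_path.rsplit("[", 1)[1][:-1]
                for el in root.iter(_NS + "cell"):
                    if el.get("id") == cid:
                        target = el
                        break
            elif "/channel_type[" in parent_path:
                cid = parent_path.rsplit("[", 1)[1][:-1]
                for el in root.iter(_NS + "channel_type"):
                    if el.get("id") == cid:
                        target = el
                        break
            target.append(etree.fromstring(payload))
        return root

    def _metadata(self, root, md: Metadata) -> None:
        if md.comments:
            etree.SubElement(root, _NS + "notes").text = md.comments
        for attr in ("authors", "translators"):
            people = getattr(md, attr)
            if people:
                el = etree.SubElement(root, _NS + attr)
                for p in people:
                    pe = etree.SubElement(el, _NS + "person")
                    pe.set("name", p.name)
                    if p.institution:
                        pe.set("institution", p.institution)
        if md.publications:
            el = etree.SubElement(root, _NS + "publications")
            for pub in md.publications:
                etree.SubElement(el, _NS + "publication").text = pub
        if md.database_refs:
            el = etree.SubElement(root, _NS + "database_refs")
            for db, acc in md.database_refs:
                re_ = etree.SubElement(el, _NS + "database_ref")
                re_.set("database", db)
                re_.set("accession", acc)
        if md.status or md.status_comment:
            el = etree.SubElement(root, _NS + "status")
            if md.status:
                el.set("value", md.status)
            el.text = md.status_comment

    def _cell(self, parent, cell: CellLike) -> None:
        morph = (cell.morphology if isinstance(cell, BiophysicalCell)
                 else cell)
        el = etree.SubElement(parent, _NS + "cell")
        el.set("id", morph.id)
        if morph.metadata.comments:
            etree.SubElement(el, _NS + "notes").text = \
                morph.metadata.comments
        segs = etree.SubElement(el, _NS + "segments")
        L = Dimension.LENGTH
        for seg in morph.segments:
            s_el = etree.SubElement(segs, _NS + "segment")
            s_el.set("id", seg.id)
            if seg.name:
                s_el.set("name", seg.name)
            if seg.parent is not None:
                s_el.set("parent", seg.parent)
            s_el.set("cable", seg.cable)
            for tag, point in (("proximal", seg.proximal),
                               ("distal", seg.distal)):
                if point is None:
                    continue
                p_el = etree.SubElement(s_el, _NS + tag)
                p_el.set("x", self.q(point.x, L))
                p_el.set("y", self.q(point.y, L))
                p_el.set("z", self.q(point.z, L))
                p_el.set("diameter", self.q(point.diameter, L))
        cabs = etree.SubElement(el, _NS + "cables")
        for cab in morph.cables:
            c_el = etree.SubElement(cabs, _NS + "cable")
            c_el.set("id", cab.id)
            if cab.name:
                c_el.set("name", cab.name)
            c_el.set("segments", " ".join(cab.segment_ids))
            c_el.set("internal_divisions", str(cab.internal_divisions))
            for g in sorted(cab.groups):
                etree.SubElement(c_el, _NS + "group").text = g
        if isinstance(cell, BiophysicalCell):
            bio = etree.SubElement(el, _NS + "biophysics")
            for tag, table, dim in (
                    ("specific_capacitance", cell.specific_capacitance,
                     Dimension.SPECIFIC_CAPACITANCE),
                    ("axial_resistivity", cell.axial_resistivity,
                     Dimension.RESISTIVITY)):
                t_el = etree.SubElement(bio, _NS + tag)
                for group, value in table.items():
                    v_el = etree.SubElement(t_el, _NS + "value")
                    v_el.set("group", group)
                    v_el.set("value", self.q(value, dim))
            for pl in cell.mechanism_placements:
                m_el = etree.SubElement(bio, _NS + "mechanism")
                m_el.set("channel", pl.channel_id)
                if isinstance(pl.density, VariableParameter):
                    d_el = etree.SubElement(m_el, _NS + "variable_density")
                    d_el.set("metric", pl.density.metric)
                    d_el.set("expression", pl.density.expression)
                    d_el.set("group", sorted(pl.groups)[0])
                else:
                    d_el = etree.SubElement(m_el, _NS + "density")
                    d_el.set("value", self.q(
                        pl.density, Dimension.SPECIFIC_CONDUCTANCE))
                    d_el.set("group", sorted(pl.groups)[0])
            for pp in cell.ion_pool_placements:
                p_el = etree.SubElement(bio, _NS + "ion_pool")
                p_el.set("pool", pp.pool_id)
                p_el.set("group", sorted(pp.groups)[0])
            if cell.connectivity:
                conn = etree.SubElement(el, _NS + "connectivity")
                for sid, groups in cell.connectivity.items():
                    for g in sorted(groups):
                        l_el = etree.SubElement(conn,
                                                _NS + "potential_syn_loc")
                        l_el.set("synapse", sid)
                        l_el.set("group", g)

    def _rate_law(self, parent, tag: str, law: ch.RateLaw) -> None:
        el = etree.SubElement(parent, _NS + tag)
        el.set("form", law.form)
        if law.form == "generic":
            el.set("expression", law.expression or "")
        else:
            el.set("rate", self.q(law.rate, "inverse-time"))
            el.set("scale", self.q(law.scale, "inverse-voltage"))
            el.set("midpoint", self.q(law.midpoint, Dimension.VOLTAGE))

    def _channel(self, parent, channel: ch.ChannelType) -> None:
        el = etree.SubElement(parent, _NS + "channel_type")
        el.set("id", channel.id)
        el.set("default_gmax", self.q(channel.max_conductance_density,
                                      Dimension.SPECIFIC_CONDUCTANCE))
        el.set("default_erev", self.q(channel.reversal_potential,
                                      Dimension.VOLTAGE))
        if channel.ion:
            el.set("ion", channel.ion)
        if channel.passive:
            el.set("passive", "true")
        if channel.q10 is not None:
            q_el = etree.SubElement(el, _NS + "q10")
            q_el.set("factor", _fmt(channel.q10.q10_factor))
            q_el.set("experimental_temp",
                     self.q(channel.q10.experimental_temp,
                            Dimension.TEMPERATURE))
        for gate in channel.gates:
            g_el = etree.SubElement(el, _NS + "gate")
            g_el.set("name", gate.name)
            g_el.set("instances", str(gate.instances))
            if gate.ligand_gated:
                g_el.set("ligand_gated", "true")
            self._rate_law(g_el, "forward", gate.forward)
            self._rate_law(g_el, "backward", gate.backward)
        if channel.scheme is not None:
            k_el = etree.SubElement(el, _NS + "kinetic_scheme")
            for state in channel.scheme.states:
                s_el = etree.SubElement(k_el, _NS + "state")
                s_el.set("id", state.id)
                s_el.set("open", "true" if state.open else "false")
            for tr in channel.scheme.transitions:
                t_el = etree.SubElement(k_el, _NS + "transition")
                t_el.set("from", tr.from_state)
                t_el.set("to", tr.to_state)
                t_el.set("form", tr.rate.form)
                if tr.rate.form == "generic":
                    t_el.set("expression", tr.rate.expression or "")
                else:
                    t_el.set("rate", self.q(tr.rate.rate, "inverse-time"))
                    t_el.set("scale", self.q(tr.rate.scale,
                                             "inverse-voltage"))
                    t_el.set("midpoint", self.q(tr.rate.midpoint,
                                                Dimension.VOLTAGE))

    def _iaf(self, parent, mech: ch.IaFMechanism) -> None:
        el = etree.SubElement(parent, _NS + "integrate_and_fire")
        el.set("id", mech.id)
        el.set("threshold", self.q(mech.threshold, Dimension.VOLTAGE))
        el.set("reset", self.q(mech.reset, Dimension.VOLTAGE))
        el.set("refractory", self.q(mech.refractory, Dimension.TIME))
        el.set("leak_conductance", self.q(
            mech.leak_conductance, Dimension.SPECIFIC_CONDUCTANCE))
        el.set("leak_reversal", self.q(mech.leak_reversal,
                                       Dimension.VOLTAGE))

    def _double_exp(self, parent, s: syn.DoubleExpSynapse) -> None:
        el = etree.SubElement(parent, _NS + "double_exp_syn")
        el.set("max_conductance", self.q(s.max_conductance,
                                         Dimension.CONDUCTANCE))
        el.set("reversal", self.q(s.reversal, Dimension.VOLTAGE))
        el.set("rise_time", self.q(s.rise_time, Dimension.TIME))
        for tau, frac in zip(s.decay_times, s.decay_fractions):
            d_el = etree.SubElement(el, _NS + "decay")
            d_el.set("tau", self.q(tau, Dimension.TIME))
            d_el.set("fraction", _fmt(frac))

    def _synapse(self, parent, s: syn.SynapseType) -> None:
        el = etree.SubElement(parent, _NS + "synapse_type")
        el.set("id", s.id)
        if isinstance(s, syn.DoubleExpSynapse):
            self._double_exp(el, s)
        elif isinstance(s, syn.BlockingSynapse):
            b_el = etree.SubElement(el, _NS + "blocking_syn")
            b_el.set("max_conductance", self.q(s.base.max_conductance,
                                               Dimension.CONDUCTANCE))
            b_el.set("reversal", self.q(s.base.reversal, Dimension.VOLTAGE))
            b_el.set("rise_time", self.q(s.base.rise_time, Dimension.TIME))
            for tau, frac in zip(s.base.decay_times, s.base.decay_fractions):
                d_el = etree.SubElement(b_el, _NS + "decay")
                d_el.set("tau", self.q(tau, Dimension.TIME))
                d_el.set("fraction", _fmt(frac))
            m_el = etree.SubElement(b_el, _NS + "mg_block")
            m_el.set("concentration", self.q(s.block.mg_concentration,
                                             Dimension.CONCENTRATION))
            m_el.set("eta", self.q(s.block.eta, "inverse-concentration"))
            m_el.set("gamma", self.q(s.block.gamma, "inverse-voltage"))
        elif isinstance(s, syn.STPSynapse):
            p_el = etree.SubElement(el, _NS + "stp_syn")
            p_el.set("utilisation", _fmt(s.utilisation))
            p_el.set("tau_rec", self.q(s.tau_rec, Dimension.TIME))
            p_el.set("tau_fac", self.q(s.tau_fac, Dimension.TIME))
            self._double_exp(p_el, s.base)
        elif isinstance(s, syn.STDPSynapse):
            p_el = etree.SubElement(el, _NS + "stdp_syn")
            p_el.set("w_max", _fmt(s.w_max))
            p_el.set("a_plus", _fmt(s.a_plus))
            p_el.set("a_minus", _fmt(s.a_minus))
            p_el.set("tau_plus", self.q(s.tau_plus, Dimension.TIME))
            p_el.set("tau_minus", self.q(s.tau_minus, Dimension.TIME))
            p_el.set("initial_weight", _fmt(s.initial_weight))
        elif isinstance(s, syn.GapJunction):
            g_el = etree.SubElement(el, _NS + "electrical_syn")
            g_el.set("conductance", self.q(s.conductance,
                                           Dimension.CONDUCTANCE))

    def _network(self, root, net: NetworkInstance) -> None:
        el = etree.SubElement(root, _NS + "network")
        if isinstance(net, NetworkTemplate):
            el.set("template_seed", str(net.seed))
        L = Dimension.LENGTH
        pops = etree.SubElement(el, _NS + "populations")
        for pop in net.populations:
            p_el = etree.SubElement(pops, _NS + "population")
            p_el.set("name", pop.name)
            p_el.set("cell_type", pop.cell_type)
            if pop.template is not None:
                t_el = etree.SubElement(p_el, _NS + "template")
                t_el.set("count", str(pop.template.count))
                if pop.template.min_separation:
                    t_el.set("min_separation",
                             self.q(pop.template.min_separation, L))
                region = pop.template.region
                if isinstance(region, Box):
                    r_el = etree.SubElement(t_el, _NS + "box")
                    for attr in ("x", "y", "z", "width", "height", "depth"):
                        r_el.set(attr, self.q(getattr(region, attr), L))
                else:
                    r_el = etree.SubElement(t_el, _NS + "cylinder")
                    for attr in ("x", "y", "z", "radius", "height"):
                        r_el.set(attr, self.q(getattr(region, attr), L))
                etree.SubElement(t_el, _NS + "random_placement")
            else:
                i_el = etree.SubElement(p_el, _NS + "instances")
                i_el.set("size", str(len(pop.instances)))
                for inst in pop.instances:
                    c_el = etree.SubElement(i_el, _NS + "instance")
                    c_el.set("id", str(inst.index))
                    if inst.node_id is not None:
                        c_el.set("node_id", str(inst.node_id))
                    l_el = etree.SubElement(c_el, _NS + "location")
                    l_el.set("x", self.q(inst.x, L))
                    l_el.set("y", self.q(inst.y, L))
                    l_el.set("z", self.q(inst.z, L))
        projs = etree.SubElement(el, _NS + "projections")
        for proj in net.projections:
            p_el = etree.SubElement(projs, _NS + "projection")
            p_el.set("name", proj.name)
            p_el.set("source", proj.source)
            p_el.set("target", proj.target)
            p_el.set("synapse", proj.synapse_id)
            if proj.electrical:
                p_el.set("electrical", "true")
            if proj.conductance is not None:
                p_el.set("conductance", self.q(proj.conductance,
                                               Dimension.CONDUCTANCE))
            for k, c in enumerate(proj.connections):
                c_el = etree.SubElement(p_el, _NS + "connection")
                c_el.set("id", str(k))
                c_el.set("pre_cell", str(c.pre_cell))
                c_el.set("pre_segment", c.pre_segment)
                c_el.set("pre_fraction", _fmt(c.pre_fraction))
                c_el.set("post_cell", str(c.post_cell))
                c_el.set("post_segment", c.post_segment)
                c_el.set("post_fraction", _fmt(c.post_fraction))
                c_el.set("weight", _fmt(c.weight))
                c_el.set("delay", self.q(c.delay, Dimension.TIME))
        inputs = etree.SubElement(el, _NS + "inputs")
        A = Dimension.CURRENT
        for inp in net.inputs:
            i_el = etree.SubElement(inputs, _NS + "input")
            i_el.set("name", inp.name)
            i_el.set("kind", inp.kind)
            i_el.set("population", inp.target_population)
            i_el.set("segment", inp.segment)
            i_el.set("fraction", _fmt(inp.fraction))
            if inp.kind == "current-pulse":
                i_el.set("amplitude", self.q(inp.amplitude, A))
                i_el.set("delay", self.q(inp.delay, Dimension.TIME))
                i_el.set("duration", self.q(inp.duration, Dimension.TIME))
            elif inp.kind == "continuous-random-current":
                i_el.set("amplitude_min", self.q(inp.amplitude_min, A))
                i_el.set("amplitude_max", self.q(inp.amplitude_max, A))
            else:
                i_el.set("rate", _fmt(inp.rate))
                i_el.set("synapse", inp.synapse_id)
            if inp.cells is not None:
                i_el.set("cells", " ".join(str(c) for c in inp.cells))


def serialize_document(doc: NeuroMLDocument,
                       target_system: Optional[UnitSystem] = None,
                       validate: bool = True) -> str:
    """Serialize a document to NeuroML XML in ``target_system`` units.

    Refuses (with the validation report) if the document has validation
    errors; the output re-parses to a structurally equal document.
    """
    if validate:
        report = validate_document(doc)
        if report.errors:
            raise NMLValidationError(report)
    system = target_system or doc.unit_system
    root = _Writer(doc, system).write()
    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    severity: str   # "error" | "warning"
    path: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def error(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue("error", path, message))

    def warn(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue("warning", path, message))

    def pretty(self) -> str:
        if not self.issues:
            return "document is valid"
        return "\n".join(f"{i.severity.upper()}: {i.path}: {i.message}"
                         for i in self.issues)


def validate_document(doc: NeuroMLDocument) -> ValidationReport:
    """Check every type invariant and reference constraint.

    Problems are report entries (ordered by document position), never
    exceptions.  Schema-level violations are errors; stylistic issues
    (e.g. missing metadata) are warnings.
    """
    rep = ValidationReport()
    if doc.level not in (1, 2, 3):
        rep.error("/neuroml", f"level must be 1, 2 or 3, not {doc.level}")
    if doc.metadata.is_empty():
        rep.warn("/neuroml", "document carries no metadata")
    if doc.level < 2 and (doc.channels or doc.synapses or doc.ion_pools
                          or any(isinstance(c, BiophysicalCell)
                                 for c in doc.cells)):
        rep.error("/neuroml", "membrane mechanisms and biophysics require "
                              "Level 2 or higher")
    if doc.level < 3 and doc.network is not None:
        rep.error("/neuroml", "networks require Level 3")

    mech_index = doc.mechanism_index()
    seen_cells: set[str] = set()
    for cell in doc.cells:
        morph = (cell.morphology if isinstance(cell, BiophysicalCell)
                 else cell)
        path = f"/neuroml/cells/cell[{morph.id}]"
        if morph.id in seen_cells:
            rep.error(path, f"duplicate cell id {morph.id!r}")
        seen_cells.add(morph.id)
        _validate_morphology(rep, path, morph)
        if isinstance(cell, BiophysicalCell):
            _validate_biophysics(rep, path, cell, mech_index)

    seen_mech: set[str] = set()
    for mech in doc.channels:
        path = f"/neuroml/channels/channel_type[{mech.id}]"
        if mech.id in seen_mech:
            rep.error(path, f"duplicate mechanism id {mech.id!r}")
        seen_mech.add(mech.id)
        if isinstance(mech, ch.IaFMechanism):
            if mech.reset >= mech.threshold:
                rep.error(path, "integrate-and-fire reset must lie below "
                                "threshold")
            if mech.refractory < 0:
                rep.error(path, "refractory period must be non-negative")
            continue
        if mech.gates and mech.scheme is not None:
            rep.error(path, "channel has both gates and a kinetic scheme; "
                            "they are mutually exclusive")
        if not mech.gates and mech.scheme is None and not mech.passive:
            rep.error(path, "channel needs gates, a kinetic scheme, or "
                            "passive='true'")
        if mech.q10 is not None and mech.q10.q10_factor <= 0:
            rep.error(path + "/q10", "q10 factor must be positive")
        for gate in mech.gates:
            gpath = f"{path}/gate[{gate.name}]"
            if gate.instances < 1:
                rep.error(gpath, f"gate instance count must be a positive "
                                 f"integer, not {gate.instances}")
            _validate_rate_range(rep, gpath, gate)
        if mech.scheme is not None:
            ids = [s.id for s in mech.scheme.states]
            if len(set(ids)) != len(ids):
                rep.error(path + "/kinetic_scheme", "duplicate state ids")
            for tr in mech.scheme.transitions:
                for ref in (tr.from_state, tr.to_state):
                    if ref not in ids:
                        rep.error(path + "/kinetic_scheme",
                                  f"transition references unknown state "
                                  f"{ref!r}")

    for pool in doc.ion_pools:
        path = f"/neuroml/channels/ion_concentration[{pool.id}]"
        if pool.id in seen_mech:
            rep.error(path, f"duplicate mechanism id {pool.id!r}")
        seen_mech.add(pool.id)
        if pool.resting_concentration < 0:
            rep.error(path, "resting concentration must be non-negative")

    seen_syn: set[str] = set()
    for s in doc.synapses:
        path = f"/neuroml/synapses/synapse_type[{s.id}]"
        if s.id in seen_syn:
            rep.error(path, f"duplicate synapse id {s.id!r}")
        seen_syn.add(s.id)

    if doc.network is not None:
        _validate_network(rep, doc)
    return rep


def _validate_morphology(rep: ValidationReport, path: str,
                         morph: CellMorphology) -> None:
    seg_ids = [s.id for s in morph.segments]
    if len(set(seg_ids)) != len(seg_ids):
        dup = sorted({i for i in seg_ids if seg_ids.count(i) > 1})
        rep.error(path + "/segments", f"duplicate segment id(s) {dup}")
        return
    cab_map = morph.cable_map()
    claimed: dict[str, str] = {}
    for cab in morph.cables:
        cpath = f"{path}/cables/cable[{cab.id}]"
        if cab.internal_divisions < 1:
            rep.error(cpath, "internal_divisions must be >= 1")
        for sid in cab.segment_ids:
            if sid not in set(seg_ids):
                rep.error(cpath, f"cable lists unknown segment {sid!r}")
            elif sid in claimed:
                rep.error(cpath, f"segment {sid!r} already belongs to "
                                 f"cable {claimed[sid]!r}")
            else:
                claimed[sid] = cab.id
        # unbranched-path check
        segmap = morph.segment_map()
        for prev, sid in zip(cab.segment_ids, cab.segment_ids[1:]):
            seg = segmap.get(sid)
            if seg is not None and seg.parent != prev:
                rep.error(cpath, f"segments do not form an unbranched "
                                 f"path: {sid!r} does not continue "
                                 f"{prev!r}")
    for seg in morph.segments:
        spath = f"{path}/segments/segment[{seg.id}]"
        if seg.id not in claimed:
            rep.error(spath, f"segment {seg.id!r} belongs to no cable")
        elif seg.cable != claimed[seg.id]:
            rep.error(spath, f"segment {seg.id!r} names cable "
                             f"{seg.cable!r} but is listed by "
                             f"{claimed[seg.id]!r}")
        for point in (seg.proximal, seg.distal):
            if point is not None and point.diameter < 0:
                rep.error(spath, "negative diameter")
        if seg.parent is not None and seg.parent not in set(seg_ids):
            rep.error(spath, f"unknown parent segment {seg.parent!r}")
    try:
        for finding in check_integrity(morph):
            fpath = f"{path}/segments/segment[{finding.element}]"
            if finding.kind == "cycle":
                rep.error(fpath, finding.message)
            else:
                rep.warn(fpath, finding.message)
    except Exception as exc:   # geometry too broken to walk
        rep.error(path, f"integrity check failed: {exc}")


def _validate_rate_range(rep: ValidationReport, path: str,
                         gate: ch.Gate) -> None:
    grid = np.linspace(-100.0, 60.0, 33)
    for tag, law in (("forward", gate.forward), ("backward", gate.backward)):
        try:
            ch.evaluate_rate(law, grid, ca=1e-4)
        except ch.DomainError as exc:
            rep.error(f"{path}/{tag}", str(exc))
        except Exception as exc:
            rep.error(f"{path}/{tag}", f"rate law cannot be evaluated: {exc}")


def _validate_biophysics(rep: ValidationReport, path: str,
                         cell: BiophysicalCell,
                         mech_index: dict[str, object]) -> None:
    morph = cell.morphology
    known_groups = {"all"}
    for cab in morph.cables:
        known_groups |= cab.groups
    for table, tag in ((cell.specific_capacitance, "specific_capacitance"),
                       (cell.axial_resistivity, "axial_resistivity")):
        for group in table:
            if group not in known_groups:
                rep.error(f"{path}/biophysics/{tag}",
                          f"unknown group {group!r}")
    max_d = 0.0
    try:
        from .morphology import path_distance
        for seg in morph.segments:
            max_d = max(max_d, path_distance(morph, seg.id, 1.0))
    except Exception:
        pass
    for k, pl in enumerate(cell.mechanism_placements):
        mpath = f"{path}/biophysics/mechanism[{pl.channel_id}]"
        if pl.channel_id not in mech_index:
            rep.error(mpath, f"reference to undefined mechanism "
                             f"{pl.channel_id!r}")
        for group in pl.groups:
            if group not in known_groups:
                rep.error(mpath, f"unknown group {group!r}")
        if isinstance(pl.density, VariableParameter):
            try:
                for d in np.linspace(0.0, max(max_d, 1.0), 17):
                    pl.density.evaluate(float(d))
            except Exception as exc:
                rep.error(mpath, f"variable density invalid: {exc}")
    for pp in cell.ion_pool_placements:
        ppath = f"{path}/biophysics/ion_pool[{pp.pool_id}]"
        if pp.pool_id not in mech_index:
            rep.error(ppath, f"reference to undefined ion pool "
                             f"{pp.pool_id!r}")
    for sid, groups in cell.connectivity.items():
        cpath = f"{path}/connectivity/potential_syn_loc[{sid}]"
        if sid not in mech_index:
            rep.error(cpath, f"reference to undefined synapse {sid!r}")
        for group in groups:
            if group not in known_groups:
                rep.error(cpath, f"unknown group {group!r}")


def _validate_network(rep: ValidationReport, doc: NeuroMLDocument) -> None:
    net = doc.network
    cell_index = doc.cell_index()
    mech_index = doc.mechanism_index()
    pop_names: set[str] = set()
    for pop in net.populations:
        path = f"/neuroml/network/populations/population[{pop.name}]"
        if pop.name in pop_names:
            rep.error(path, f"duplicate population name {pop.name!r}")
        pop_names.add(pop.name)
        if pop.cell_type not in cell_index:
            rep.error(path, f"reference to undefined cell type "
                            f"{pop.cell_type!r}")
        indices = [i.index for i in pop.instances]
        if len(set(indices)) != len(indices):
            rep.error(path, "duplicate instance indices")
    for proj in net.projections:
        path = f"/neuroml/network/projections/projection[{proj.name}]"
        if proj.synapse_id not in mech_index:
            rep.error(path, f"reference to undefined synapse "
                            f"{proj.synapse_id!r}")
        for ref in (proj.source, proj.target):
            if ref not in pop_names:
                rep.error(path, f"reference to undefined population "
                                f"{ref!r}")
        # post targets must respect declared connectivity groups
        if proj.target in pop_names and not proj.electrical:
            tgt_pop = net.population(proj.target)
            cell = cell_index.get(tgt_pop.cell_type)
            if isinstance(cell, BiophysicalCell) and \
                    proj.synapse_id in cell.connectivity:
                allowed = cell.connectivity[proj.synapse_id]
                for c in proj.connections:
                    try:
                        groups = cell.morphology.segment_groups(
                            c.post_segment)
                    except KeyError:
                        rep.error(path, f"connection targets unknown "
                                        f"segment {c.post_segment!r}")
                        continue
                    if not groups & allowed:
                        rep.error(path,
                                  f"connection onto segment "
                                  f"{c.post_segment!r} violates allowed "
                                  f"groups {sorted(allowed)}")
    for inp in net.inputs:
        path = f"/neuroml/network/inputs/input[{inp.name}]"
        if inp.target_population not in pop_names:
            rep.error(path, f"reference to undefined population "
                            f"{inp.target_population!r}")
        if inp.kind == "random-synaptic-events" and \
                inp.synapse_id not in mech_index:
            rep.error(path, f"reference to undefined synapse "
                            f"{inp.synapse_id!r}")
        if (inp.amplitude_max < inp.amplitude_min or inp.rate < 0
                or inp.duration < 0):
            rep.error(path, "input rates/amplitude ranges must be "
                            "non-negative and ordered")


# ---------------------------------------------------------------------------
# human-readable summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryReport:
    html: str
    #: (channel id, gate name) -> dict with v, alpha, beta, tau, inf arrays
    curves: dict[tuple[str, str], dict[str, np.ndarray]]
    warnings: list[str] = field(default_factory=list)

    def curves_tsv(self, channel_id: str, gate_name: str) -> str:
        data = self.curves[(channel_id, gate_name)]
        lines = ["v_mV\talpha_per_ms\tbeta_per_ms\ttau_ms\tinf"]
        for k in range(len(data["v"])):
            lines.append("\t".join(
                f"{data[col][k]:.9g}"
                for col in ("v", "alpha", "beta", "tau", "inf")))
        return "\n".join(lines) + "\n"


def render_summary(doc: NeuroMLDocument, v_min: float = -100.0,
                   v_max: float = 60.0, dv: float = 1.0) -> SummaryReport:
    """Generate an HTML overview plus per-gate rate/tau/inf curve tables.

    Every gate of every channel is sampled on the voltage grid; ``tau``
    and ``inf`` are derived from alpha and beta.  An empty document
    yields an empty report with a warning.
    """
    warnings: list[str] = []
    if not doc.cells and not doc.channels and not doc.synapses:
        warnings.append("document contains no cells, channels or synapses")
    grid = np.arange(v_min, v_max + dv / 2.0, dv)
    curves: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>"
        f"<title>NeuroML summary</title></head><body>",
        f"<h1>NeuroML Level {doc.level} document</h1>",
        f"<p>Unit system: {doc.unit_system.value}</p>"]
    md = doc.metadata
    if not md.is_empty():
        parts.append("<h2>Metadata</h2><ul>")
        for person in md.authors:
            parts.append(f"<li>Author: {person.name} "
                         f"({person.institution})</li>")
        for person in md.translators:
            parts.append(f"<li>Translator: {person.name}</li>")
        for pub in md.publications:
            parts.append(f"<li>Publication: {pub}</li>")
        for db, acc in md.database_refs:
            parts.append(f"<li>Database: {db} accession {acc}</li>")
        if md.comments:
            parts.append(f"<li>Notes: {md.comments}</li>")
        if md.status:
            parts.append(f"<li>Status: {md.status}</li>")
        parts.append("</ul>")
    for cell in doc.cells:
        morph = (cell.morphology if isinstance(cell, BiophysicalCell)
                 else cell)
        parts.append(f"<h2>Cell {morph.id}</h2>"
                     f"<p>{len(morph.segments)} segments in "
                     f"{len(morph.cables)} cables; surface area "
                     f"{morph.surface_area():.4g} &micro;m&sup2;</p>")
    for mech in doc.channels:
        if isinstance(mech, ch.IaFMechanism):
            parts.append(
                f"<h2>Integrate-and-fire {mech.id}</h2><table>"
                f"<tr><td>threshold</td><td>{mech.threshold} mV</td></tr>"
                f"<tr><td>reset</td><td>{mech.reset} mV</td></tr>"
                f"<tr><td>refractory</td><td>{mech.refractory} ms</td></tr>"
                f"</table>")
            continue
        parts.append(
            f"<h2>Channel {mech.id}</h2><table>"
            f"<tr><td>gmax</td><td>{mech.max_conductance_density} "
            f"mS/cm&sup2;</td></tr>"
            f"<tr><td>E<sub>rev</sub></td><td>{mech.reversal_potential} "
            f"mV</td></tr>"
            f"<tr><td>ion</td><td>{mech.ion or '-'}</td></tr></table>")
        if mech.q10 is not None:
            parts.append(f"<p>Q10 factor {mech.q10.q10_factor} at "
                         f"{mech.q10.experimental_temp} &deg;C</p>")
        for gate in mech.gates:
            try:
                alpha = ch.evaluate_rate(gate.forward, grid, ca=1e-4)
                beta = ch.evaluate_rate(gate.backward, grid, ca=1e-4)
            except ch.DomainError as exc:
                warnings.append(f"channel {mech.id} gate {gate.name}: "
                                f"{exc}")
                continue
            total = alpha + beta
            with np.errstate(divide="ignore", invalid="ignore"):
                tau = np.where(total > 0, 1.0 / total, np.inf)
                inf = np.where(total > 0, alpha / total, np.nan)
            curves[(mech.id, gate.name)] = {
                "v": grid, "alpha": np.asarray(alpha),
                "beta": np.asarray(beta), "tau": tau, "inf": inf}
            parts.append(
                f"<h3>Gate {gate.name} (x{gate.instances})</h3>"
                f"<p>alpha: {_law_text(gate.forward)}<br>"
                f"beta: {_law_text(gate.backward)}<br>"
                f"tau = 1/(alpha+beta), inf = alpha/(alpha+beta); "
                f"curves sampled on [{v_min}, {v_max}] mV</p>")
    for s in doc.synapses:
        parts.append(f"<h2>Synapse {s.id}</h2>"
                     f"<p>{type(s).__name__}</p>")
    parts.append("</body></html>")
    return SummaryReport(html="\n".join(parts), curves=curves,
                         warnings=warnings)


def _law_text(law: ch.RateLaw) -> str:
    if law.form == "generic":
        return f"expr[{law.expression}]"
    return (f"{law.form}(A={law.rate} ms<sup>-1</sup>, k={law.scale} "
            f"mV<sup>-1</sup>, d={law.midpoint} mV)")
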