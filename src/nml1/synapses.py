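"""Synaptic mechanisms: conductance waveforms, NMDA Mg2+ block, short-term
plasticity (Tsodyks-Markram), additive STDP and electrical coupling.

Conductance waveforms are peak-normalized: ``max_conductance`` is the
literal peak of a single event, so amplitudes read straight off
voltage-clamp comparisons.  Up to three decay components with fractional
amplitudes are supported; a zero rise time gives an instantaneous-rise
exponential, and a rise time equal to the (single) decay time degenerates
to the alpha function ``g_max (t/tau) exp(1 - t/tau)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar


class SynapseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# conductance waveform
# ---------------------------------------------------------------------------

@dataclass
class DoubleExpSynapse:
    """Exponential-rise, multi-exponential-decay conductance waveform.

    ``max_conductance`` in uS, ``reversal`` in mV, times in ms.
    ``decay_times`` has 1-3 entries; ``decay_fractions`` must sum to 1.
    """

    id: str
    max_conductance: float
    reversal: float
    rise_time: float
    decay_times: tuple[float, ...]
    decay_fractions: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not 1 <= len(self.decay_times) <= 3:
            raise SynapseError("1 to 3 decay components required")
        if len(self.decay_fractions) != len(self.decay_times):
            raise SynapseError("one fraction per decay component")
        if abs(sum(self.decay_fractions) - 1.0) > 1e-9:
            raise SynapseError("decay fractions must sum to 1")
        if any(t <= 0 for t in self.decay_times):
            raise SynapseError("decay time constants must be positive")
        if self.rise_time < 0:
            raise SynapseError("rise time must be non-negative")
        self._norm, self._alpha_tau = self._normalization()

    def _waveform_raw(self, t):
        """Unnormalized sum of decays minus rise, valid for rise > 0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for tau_d, frac in zip(self.decay_times, self.decay_fractions):
            out += frac * np.exp(-t / tau_d)
        out -= np.exp(-t / self.rise_time)
        return out

    def _normalization(self) -> tuple[float, Optional[float]]:
        if self.rise_time == 0.0:
            return 1.0, None   # peak is at t=0 and equals sum of fractions
        if (len(self.decay_times) == 1
                and abs(self.rise_time - self.decay_times[0]) < 1e-12):
            return 1.0, self.decay_times[0]   # alpha-function limit
        if len(self.decay_times) == 1:
            tau_r, tau_d = self.rise_time, self.decay_times[0]
            t_peak = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
        else:
            upper = 5.0 * max(self.decay_times)
            res = minimize_scalar(lambda t: -self._waveform_raw(t),
                                  bounds=(0.0, upper), method="bounded",
                                  options={"xatol": 1e-12})
            t_peak = float(res.x)
        peak = float(self._waveform_raw(t_peak))
        if peak <= 0:
            raise SynapseError("degenerate waveform: non-positive peak")
        return 1.0 / peak, None

    def conductance_at(self, t_since_event) -> float | np.ndarray:
        """Conductance (uS) at time ``t_since_event`` (ms) after an event.

        Events superpose linearly; callers sum over events.
        """
        t = np.asarray(t_since_event, dtype=float)
        if np.any(t < 0):
            raise SynapseError("time since event must be non-negative")
        if self._alpha_tau is not None:
            tau = self._alpha_tau
            g = self.max_conductance * (t / tau) * np.exp(1.0 - t / tau)
        elif self.rise_time == 0.0:
            g = np.zeros_like(t)
            for tau_d, frac in zip(self.decay_times, self.decay_fractions):
                g += frac * np.exp(-t / tau_d)
            g *= self.max_conductance
        else:
            g = self.max_conductance * self._norm * self._waveform_raw(t)
            g = np.maximum(g, 0.0)
        return g if np.ndim(t_since_event) else float(g)


def conductance_at(syn: DoubleExpSynapse, t_since_event):
    return syn.conductance_at(t_since_event)


# ---------------------------------------------------------------------------
# NMDA Mg2+ block
# ---------------------------------------------------------------------------

@dataclass
class MgBlock:
    """Voltage-dependent magnesium block of the NMDA receptor.

    block(v) = 1 / (1 + eta [Mg] exp(-gamma v)); in (0, 1] for finite v,
    monotonically increasing with depolarization.
    """

    mg_concentration: float   # mM
    eta: float                # mM^-1
    gamma: float              # mV^-1

    def factor(self, v) -> float | np.ndarray:
        v_arr = np.asarray(v, dtype=float)
        out = 1.0 / (1.0 + self.eta * self.mg_concentration
                     * np.exp(-self.gamma * v_arr))
        return out if np.ndim(v) else float(out)


def mg_block_factor(block: MgBlock, v):
    return block.factor(v)


@dataclass
class BlockingSynapse:
    """A conductance waveform gated by a voltage-dependent block
    (NMDA-receptor style)."""

    base: DoubleExpSynapse
    block: MgBlock

    @property
    def id(self) -> str:
        return self.base.id


# ---------------------------------------------------------------------------
# short-term plasticity (Tsodyks-Markram)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STPState:
    """Per-connection resources x, utilisation u, and last spike time."""

    x: float = 1.0
    u: float = 0.0
    last_spike: Optional[float] = None


@dataclass
class STPSynapse:
    """Tsodyks-Markram short-term plasticity wrapped around a base synapse.

    Between spikes, resources ``x`` recover toward 1 with ``tau_rec``
    (instantly when ``tau_rec = 0``) and utilisation ``u`` decays toward
    ``U`` with ``tau_fac`` (pinned at ``U`` when ``tau_fac = 0``).  On a
    spike, ``u <- u + U (1 - u)`` (facilitation, when ``tau_fac > 0``),
    the released fraction is ``u x``, then ``x <- x - u x``.  The event
    conductance is scaled by ``release / U`` so that with both time
    constants zero every spike releases exactly the base amplitude.
    """

    base: DoubleExpSynapse
    utilisation: float          # U in [0, 1]
    tau_rec: float = 0.0        # ms
    tau_fac: float = 0.0        # ms

    def __post_init__(self) -> None:
        if not 0.0 < self.utilisation <= 1.0:
            raise SynapseError("utilisation U must lie in (0, 1]")
        if self.tau_rec < 0 or self.tau_fac < 0:
            raise SynapseError("STP time constants must be non-negative")

    @property
    def id(self) -> str:
        return self.base.id

    def initial_state(self) -> STPState:
        return STPState(x=1.0, u=self.utilisation, last_spike=None)

    def on_spike(self, state: STPState, t_spike: float,
                 ) -> tuple[float, STPState]:
        """Process a presynaptic spike; returns (release fraction, state)."""
        u, x = state.u, state.x
        if state.last_spike is not None:
            if t_spike <= state.last_spike:
                raise SynapseError("spike times must be strictly increasing")
            dt = t_spike - state.last_spike
            if self.tau_rec > 0:
                x = 1.0 - (1.0 - x) * math.exp(-dt / self.tau_rec)
            else:
                x = 1.0
            if self.tau_fac > 0:
                u = (self.utilisation
                     + (u - self.utilisation) * math.exp(-dt / self.tau_fac))
            else:
                u = self.utilisation
        if self.tau_fac > 0:
            u = u + self.utilisation * (1.0 - u)
        release = u * x
        x = x - release
        return release, STPState(x=x, u=u, last_spike=t_spike)

    def event_scale(self, release: float) -> float:
        """Factor applied to the base conductance for this event."""
        return release / self.utilisation


def stp_on_spike(syn: STPSynapse, state: STPState, t_spike: float,
                 ) -> tuple[float, STPState]:
    return syn.on_spike(state, t_spike)


# ---------------------------------------------------------------------------
# spike-timing-dependent plasticity (additive, Song & Abbott)
# ---------------------------------------------------------------------------

@dataclass
class STDPState:
    weight: float
    pre_trace: float = 0.0
    post_trace: float = 0.0
    t_pre: float = -math.inf
    t_post: float = -math.inf


@dataclass
class STDPSynapse:
    """Additive trace-based STDP with hard weight bounds [0, w_max].

    A pre spike followed by a post spike at lag dt potentiates the weight
    by ``a_plus exp(-dt/tau_plus) w_max``; post-before-pre depresses by
    ``a_minus exp(-dt/tau_minus) w_max``.  All-to-all pairing via
    exponentially decaying traces.
    """

    id: str
    w_max: float
    a_plus: float
    a_minus: float
    tau_plus: float
    tau_minus: float
    initial_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise SynapseError("STDP time constants must be positive")
        if not 0.0 <= self.initial_weight <= self.w_max:
            raise SynapseError("initial weight outside [0, w_max]")

    def initial_state(self) -> STDPState:
        return STDPState(weight=self.initial_weight)

    def _clip(self, w: float) -> float:
        return min(max(w, 0.0), self.w_max)

    # Each trace is stored at the time of its own last event (t_pre for
    # the pre trace, t_post for the post trace) and decayed transiently
    # when the opposite stream samples it.

    def on_pre(self, state: STDPState, t: float) -> STDPState:
        if t < state.t_pre:
            raise SynapseError("pre event times must be non-decreasing")
        post = state.post_trace * math.exp(-(t - state.t_post) / self.tau_minus) \
            if state.t_post > -math.inf else 0.0
        pre = state.pre_trace * math.exp(-(t - state.t_pre) / self.tau_plus) \
            if state.t_pre > -math.inf else 0.0
        w = self._clip(state.weight - self.a_minus * self.w_max * post)
        return STDPState(weight=w, pre_trace=pre + 1.0,
                         post_trace=state.post_trace,
                         t_pre=t, t_post=state.t_post)

    def on_post(self, state: STDPState, t: float) -> STDPState:
        if t < state.t_post:
            raise SynapseError("post event times must be non-decreasing")
        pre = state.pre_trace * math.exp(-(t - state.t_pre) / self.tau_plus) \
            if state.t_pre > -math.inf else 0.0
        post = state.post_trace * math.exp(-(t - state.t_post) / self.tau_minus) \
            if state.t_post > -math.inf else 0.0
        w = self._clip(state.weight + self.a_plus * self.w_max * pre)
        return STDPState(weight=w, pre_trace=state.pre_trace,
                         post_trace=post + 1.0,
                         t_pre=state.t_pre, t_post=t)


def stdp_on_pre(syn: STDPSynapse, state: STDPState, t: float) -> STDPState:
    return syn.on_pre(state, t)


def stdp_on_post(syn: STDPSynapse, state: STDPState, t: float) -> STDPState:
    return syn.on_post(state, t)


# ---------------------------------------------------------------------------
# electrical synapse
# ---------------------------------------------------------------------------

@dataclass
class GapJunction:
    """Ohmic electrical coupling between two compartments."""

    id: str
    conductance: float   # uS

    def __post_init__(self) -> None:
        if self.conductance < 0:
            raise SynapseError("gap-junction conductance must be >= 0")

    def current_into_a(self, v_a: float, v_b: float) -> float:
        """Current (nA) flowing into side a; side b receives the exact
        negative (charge conservation)."""
        return self.conductance * (v_b - v_a)


def gap_current(gj: GapJunction, v_a: float, v_b: float) -> float:
    return gj.current_into_a(v_a, v_b)


#: any synapse model storable in a document
SynapseType = (DoubleExpSynapse | BlockingSynapse | STPSynapse
               | STDPSynapse | GapJunction)
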