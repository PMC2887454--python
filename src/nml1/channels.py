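"""Distributed membrane conductances: Hodgkin-Huxley gates, Markov kinetic
schemes, Q10 temperature scaling, decaying Ca2+ pools and integrate-and-fire.

Rate laws follow the canonical ChannelML v1.x triad.  With ``A`` the rate
(ms^-1), ``k`` the inverse scale (mV^-1, sign carries direction) and ``d``
the midpoint (mV), writing ``x = k (v - d)``::

    exponential:  A * exp(x)
    sigmoid:      A / (1 + exp(x))
    exp_linear:   A * x / (1 - exp(-x))      (-> A as v -> d)

The removable singularity of ``exp_linear`` at ``v = d`` is filled by its
limit inside a +-1e-7 mV guard band.  Arbitrary voltage/ligand dependence
is available through the ``generic`` form, a safe arithmetic expression in
``v``, ``ca`` and ``celsius``.

Q10 scaling multiplies any rate by ``q10_factor ** ((T - T_exp) / 10)``.

A Hodgkin-Huxley gate is the two-state special case of a Markov kinetic
scheme; :func:`scheme_step` propagates occupancies with the exact matrix
exponential so probability is conserved to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .expressions import Expression

#: voltage band (mV) around the exp_linear midpoint treated as the limit
EXP_LINEAR_GUARD = 1e-7

RATE_FORMS = ("exponential", "sigmoid", "exp_linear", "generic")


class ChannelError(ValueError):
    pass


class DomainError(ChannelError):
    """A rate law evaluated non-finite at some voltage."""


@dataclass
class Q10Settings:
    """Temperature scaling of transition rates."""

    q10_factor: float
    experimental_temp: float   # degC
    # q10_factor must be positive; checked by the document validator so
    # that invalid documents can be constructed and reported on.

    def factor(self, temp: Optional[float]) -> float:
        if temp is None:
            return 1.0
        if self.q10_factor <= 0:
            raise ChannelError("q10_factor must be positive")
        return self.q10_factor ** ((temp - self.experimental_temp) / 10.0)


@dataclass
class RateLaw:
    """A voltage (and optionally ligand) dependent transition rate."""

    form: str
    rate: float = 1.0        # A, ms^-1
    scale: float = 0.0       # k, mV^-1 (sign carries direction)
    midpoint: float = 0.0    # d, mV
    expression: Optional[str] = None   # for form == "generic"

    def __post_init__(self) -> None:
        if self.form not in RATE_FORMS:
            raise ChannelError(f"unknown rate-law form {self.form!r}")
        if self.form == "generic":
            if not self.expression:
                raise ChannelError("generic rate law requires an expression")
            self._compiled = Expression(self.expression,
                                        variables=("v", "ca", "celsius"))
        elif self.expression:
            raise ChannelError(
                f"form {self.form!r} does not take an expression")


def evaluate_rate(law: RateLaw, v, ca=None, temp: Optional[float] = None,
                  q10: Optional[Q10Settings] = None):
    """Evaluate a rate law at membrane potential ``v`` (mV) -> ms^-1.

    ``v`` may be a scalar or a numpy array.  Raises :class:`DomainError`
    if the result is non-finite or negative anywhere.
    """
    v_arr = np.asarray(v, dtype=float)
    if law.form == "generic":
        env = {"v": v_arr}
        if "ca" in law._compiled.variables:
            env["ca"] = np.asarray(0.0 if ca is None else ca, dtype=float)
        if "celsius" in law._compiled.variables:
            env["celsius"] = np.asarray(
                0.0 if temp is None else temp, dtype=float)
        out = np.asarray(law._compiled(**env), dtype=float)
        out = np.broadcast_to(out, v_arr.shape).copy()
    else:
        x = law.scale * (v_arr - law.midpoint)
        if law.form == "exponential":
            out = law.rate * np.exp(x)
        elif law.form == "sigmoid":
            out = law.rate / (1.0 + np.exp(x))
        else:  # exp_linear
            guard = np.abs(v_arr - law.midpoint) < EXP_LINEAR_GUARD
            x_safe = np.where(guard, 1.0, x)
            out = np.where(guard, law.rate,
                           law.rate * x_safe / (1.0 - np.exp(-x_safe)))
    if not np.all(np.isfinite(out)) or np.any(out < 0):
        bad = v_arr[~(np.isfinite(out) & (out >= 0))] if v_arr.shape else v_arr
        raise DomainError(
            f"{law.form} rate law is invalid at v={np.atleast_1d(bad)[:3]} mV")
    if q10 is not None:
        out = out * q10.factor(temp)
    return out if np.ndim(v) else float(out)


def rate_function(law: RateLaw, q10_scale: float = 1.0,
                  temp: Optional[float] = None):
    """Compile a rate law into a fast vectorized closure ``f(v, ca)``.

    Skips the per-call domain checking of :func:`evaluate_rate` (callers
    validate the law over the physiological range once, up front); used
    by the simulator's inner loop.
    """
    if law.form == "generic":
        compiled = law._compiled
        wants_ca = "ca" in compiled.variables
        wants_t = "celsius" in compiled.variables

        def generic(v, ca=None):
            env = {"v": v}
            if wants_ca:
                env["ca"] = ca if ca is not None else 0.0
            if wants_t:
                env["celsius"] = temp if temp is not None else 0.0
            return q10_scale * compiled(**env)
        return generic
    a = law.rate * q10_scale
    k, d = law.scale, law.midpoint
    if law.form == "exponential":
        return lambda v, ca=None: a * np.exp(k * (v - d))
    if law.form == "sigmoid":
        return lambda v, ca=None: a / (1.0 + np.exp(k * (v - d)))

    def exp_linear(v, ca=None):
        x = k * (np.asarray(v) - d)
        guard = np.abs(np.asarray(v) - d) < EXP_LINEAR_GUARD
        x = np.where(guard, 1.0, x)
        return np.where(guard, a, a * x / (1.0 - np.exp(-x)))
    return exp_linear


@dataclass
class Gate:
    """A gating particle with open/closed states and alpha/beta rates.

    ``instances`` is the power to which the state variable is raised in
    the conductance product (e.g. 4 for the classic K+ n-gate).
    """

    name: str
    instances: int        # must be >= 1; reported by the document validator
    forward: RateLaw      # alpha: closed -> open
    backward: RateLaw     # beta:  open -> closed
    ligand_gated: bool = False


def tau_inf(gate: Gate, v, ca=None, temp: Optional[float] = None,
            q10: Optional[Q10Settings] = None):
    """Time constant ``1/(alpha+beta)`` (ms) and steady state
    ``alpha/(alpha+beta)`` of a gate at ``v`` (mV)."""
    alpha = evaluate_rate(gate.forward, v, ca, temp, q10)
    beta = evaluate_rate(gate.backward, v, ca, temp, q10)
    total = np.asarray(alpha) + np.asarray(beta)
    if np.any(total <= 0):
        raise DomainError(
            f"gate {gate.name!r}: alpha + beta is zero (degenerate point)")
    tau = 1.0 / total
    inf = np.asarray(alpha) / total
    if np.ndim(v):
        return tau, inf
    return float(tau), float(inf)


def gate_derivative(gate: Gate, m, v, ca=None, temp: Optional[float] = None,
                    q10: Optional[Q10Settings] = None):
    """dm/dt = alpha (1 - m) - beta m  (ms^-1)."""
    alpha = evaluate_rate(gate.forward, v, ca, temp, q10)
    beta = evaluate_rate(gate.backward, v, ca, temp, q10)
    return alpha * (1.0 - np.asarray(m)) - beta * np.asarray(m)


# ---------------------------------------------------------------------------
# kinetic (Markov) schemes
# ---------------------------------------------------------------------------

@dataclass
class SchemeState:
    id: str
    open: bool = False


@dataclass
class SchemeTransition:
    from_state: str
    to_state: str
    rate: RateLaw


@dataclass
class KineticScheme:
    states: list[SchemeState]
    transitions: list[SchemeTransition]

    def state_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.states)}

    def rate_matrix(self, v, ca=None, temp: Optional[float] = None,
                    q10: Optional[Q10Settings] = None) -> np.ndarray:
        """Generator matrix Q with Q[i, j] = rate i -> j (ms^-1)."""
        idx = self.state_index()
        n = len(self.states)
        q = np.zeros((n, n))
        for tr in self.transitions:
            rate = evaluate_rate(tr.rate, v, ca, temp, q10)
            if rate < 0:
                raise ChannelError("negative transition rate")
            i, j = idx[tr.from_state], idx[tr.to_state]
            q[i, j] += rate
            q[i, i] -= rate
        return q

    def open_fraction(self, occupancies: Sequence[float]) -> float:
        occ = np.asarray(occupancies, dtype=float)
        mask = np.array([s.open for s in self.states])
        return float(occ[mask].sum())


def scheme_step(scheme: KineticScheme, occupancies, v, dt: float,
                ca=None, temp: Optional[float] = None,
                q10: Optional[Q10Settings] = None) -> np.ndarray:
    """Propagate a probability vector one step under the rate matrix.

    Uses the exact matrix exponential of the generator (rates frozen at
    ``v`` over the step), so the result remains a probability vector to
    1e-12 for any dt.
    """
    occ = np.asarray(occupancies, dtype=float)
    if occ.shape != (len(scheme.states),):
        raise ChannelError("occupancy vector length mismatch")
    if abs(occ.sum() - 1.0) > 1e-9 or np.any(occ < -1e-12):
        raise ChannelError("occupancies must form a probability vector")
    q = scheme.rate_matrix(v, ca, temp, q10)
    prop = scipy.linalg.expm(q * dt)
    out = occ @ prop
    np.clip(out, 0.0, 1.0, out=out)
    return out / out.sum()


def hh_gate_as_scheme(gate: Gate) -> KineticScheme:
    """The two-state kinetic scheme equivalent to an HH gate."""
    return KineticScheme(
        states=[SchemeState("closed", open=False),
                SchemeState("open", open=True)],
        transitions=[
            SchemeTransition("closed", "open", gate.forward),
            SchemeTransition("open", "closed", gate.backward)])


# ---------------------------------------------------------------------------
# channel, calcium pool, integrate-and-fire
# ---------------------------------------------------------------------------

#: uS of conductance per (mS/cm^2 density * um^2 area)
DENSITY_TO_US = 1e-5


@dataclass
class ChannelType:
    """A distributed conductance: HH gates or a kinetic scheme (not both).

    ``max_conductance_density`` in mS/cm^2, ``reversal_potential`` in mV.
    A passive (leak) conductance has neither gates nor scheme and
    ``passive=True``.
    """

    id: str
    max_conductance_density: float
    reversal_potential: float
    gates: list[Gate] = field(default_factory=list)
    scheme: Optional[KineticScheme] = None
    q10: Optional[Q10Settings] = None
    passive: bool = False
    ion: str = ""
    # invariant (reported by the document validator): gates xor scheme,
    # unless the channel is passive


def channel_current(channel: ChannelType, gate_states, v: float,
                    area: float) -> float:
    """Membrane current (nA) through a channel population.

    ``gate_states`` is one value per gate (each raised to its
    ``instances`` power), or the occupancy vector for a kinetic scheme.
    ``area`` is the compartment membrane area in um^2.  Outward current
    is positive.
    """
    g_max = channel.max_conductance_density * area * DENSITY_TO_US  # uS
    if channel.scheme is not None:
        factor = channel.scheme.open_fraction(gate_states)
    elif channel.gates:
        states = np.atleast_1d(np.asarray(gate_states, dtype=float))
        if states.shape != (len(channel.gates),):
            raise ChannelError(
                f"channel {channel.id!r}: expected {len(channel.gates)} "
                f"gate state(s), got {states.shape}")
        factor = 1.0
        for gate, m in zip(channel.gates, states):
            factor *= float(m) ** gate.instances
    else:
        factor = 1.0
    return g_max * factor * (v - channel.reversal_potential)


@dataclass
class IonConcentrationModel:
    """Exponentially decaying intracellular Ca2+ pool.

    d[Ca]/dt = -([Ca] - resting)/tau + phi * I_Ca, with ``phi`` the
    per-compartment influx scaling (mM per nA*ms; inward calcium current
    taken positive here).
    """

    id: str
    resting_concentration: float   # mM
    decay_time_constant: float     # ms
    influx_scaling: float          # mM / (nA ms)

    def __post_init__(self) -> None:
        if self.decay_time_constant <= 0:
            raise ChannelError("decay time constant must be positive")


def ca_pool_derivative(pool: IonConcentrationModel, c: float,
                       i_ca: float) -> float:
    """d[Ca]/dt (mM/ms) given concentration ``c`` and calcium influx
    current ``i_ca`` (nA, inward positive)."""
    return (-(c - pool.resting_concentration) / pool.decay_time_constant
            + pool.influx_scaling * i_ca)


def ca_pool_step(pool: IonConcentrationModel, c: float, i_ca: float,
                 dt: float) -> float:
    """Exact exponential update over one step with i_ca held constant."""
    c_inf = (pool.resting_concentration
             + pool.influx_scaling * pool.decay_time_constant * i_ca)
    c_new = c_inf + (c - c_inf) * math.exp(-dt / pool.decay_time_constant)
    return max(c_new, 0.0)


@dataclass
class IaFMechanism:
    """Basic integrate-and-fire: leaky membrane, threshold/reset/refractory."""

    id: str
    threshold: float          # mV
    reset: float              # mV; must lie below threshold (validator check)
    refractory: float         # ms, non-negative
    leak_conductance: float   # mS/cm^2
    leak_reversal: float      # mV
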