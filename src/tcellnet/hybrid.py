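"""Continuous CD80/86 affinity competition coupled to the discrete engine.

The stimulatory capacity of the CD80/86 ligands shifts over time from the
costimulatory receptor CD28 toward the higher-affinity CTLA-4 dimers.  The
capacity is a continuous variable c(t) in [0, 1] obeying a logistic decay

    dc/dt = -beta * c * (1 - c),

whose closed form is the falling sigmoid

    c(t) = 1 / (exp(beta * (t - t_d)) + 1),

with c(t_d) = 1/2 at the half-decay time t_d.  The anticorrelated linkage
strength of the CD80/86–CTLA-4-dimer complex is 1 - c(t).  At reaction rate
beta >> 1 the sigmoid is effectively a step at t_d.

One discrete update step corresponds to one unit of continuous time.  At each
step the hybrid node's Boolean value is imposed as the threshold
discretization c(t) >= theta before the synchronous update (Glass-style
piecewise coupling); no numerical integration is needed on the main path
because the closed form is evaluated on the integer grid.

A note on the rate sign: with a positive rate the logistic ODE grows toward
saturation, which contradicts the decaying closed form and the affinity-shift
phenomenology; the decaying (negative) right-hand side is therefore the
default, and the growing variant is available behind ``printed_sign=True``
for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Network, State, Trajectory, step_sync

__all__ = [
    "HybridSpec",
    "HybridTrace",
    "HybridConfigError",
    "logistic_value",
    "logistic_rhs",
    "discretize",
    "integrate_logistic",
    "hybrid_simulate",
    "ACTIVATION_MARKERS",
]

#: Transcription-factor readout whose joint activity defines full activation.
ACTIVATION_MARKERS = ("IL2G", "AP1", "NFAT", "NFKB")


class HybridConfigError(ValueError):
    """The network has no declared hybrid node (or the spec is invalid)."""


@dataclass
class HybridSpec:
    """Parameters of the affinity-competition switch.

    beta : reaction rate per time step (dimensionless); default 50, i.e. an
        effectively step-like switch.
    t_d : half-decay time in discrete steps; ``math.inf`` disables the decay.
    theta : discretization threshold in (0, 1); ties (c == theta) map to 1.
    """

    beta: float = 50.0
    t_d: float = 10.0
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise HybridConfigError("beta must be > 0")
        if not (0 < self.theta < 1):
            raise HybridConfigError("theta must lie in (0, 1)")
        if self.t_d < 0:
            raise HybridConfigError("t_d must be >= 0")


@dataclass
class HybridTrace:
    """Per-step record of the continuous variable and its discretization."""

    times: list[int] = field(default_factory=list)
    cd8086_continuous: list[float] = field(default_factory=list)
    cd8086_discrete: list[int] = field(default_factory=list)

    @property
    def ctla4dim_strength(self) -> list[float]:
        """Linkage strength of the CTLA-4-dimer complex, 1 - c(t)."""
        return [1.0 - c for c in self.cd8086_continuous]


def logistic_value(t: float, spec: HybridSpec) -> float:
    """c(t) = 1 / (exp(beta (t - t_d)) + 1), overflow-safe for large |arg|."""
    if math.isinf(spec.t_d):
        return 1.0
    arg = spec.beta * (t - spec.t_d)
    if arg > 700.0:
        return math.exp(-arg)  # underflows to 0.0 where appropriate
    return 1.0 / (math.exp(arg) + 1.0)


def logistic_rhs(c: float, spec: HybridSpec, printed_sign: bool = False) -> float:
    """Right-hand side of the logistic ODE at capacity ``c``.

    Default is the decaying form -beta c (1 - c), consistent with the falling
    sigmoid closed form; ``printed_sign=True`` gives +beta c (1 - c).
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("capacity must lie in [0, 1]")
    rhs = spec.beta * c * (1.0 - c)
    return rhs if printed_sign else -rhs


def discretize(c: float, theta: float) -> int:
    """Threshold discretization: 1 iff c >= theta (ties go to 1)."""
    return 1 if c >= theta else 0


def integrate_logistic(
    c0: float, spec: HybridSpec, t_max: float, dt: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of the decaying logistic ODE.

    Used only for validating the closed form; the simulator itself evaluates
    c(t) analytically.
    """
    n = int(round(t_max / dt))
    ts = np.linspace(0.0, n * dt, n + 1)
    cs = np.empty(n + 1)
    cs[0] = c0
    c = c0
    f = lambda x: -spec.beta * x * (1.0 - x)
    for i in range(n):
        k1 = f(c)
        k2 = f(c + 0.5 * dt * k1)
        k3 = f(c + 0.5 * dt * k2)
        k4 = f(c + dt * k3)
        c = c + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        c = min(max(c, 0.0), 1.0)
        cs[i + 1] = c
    return ts, cs


def hybrid_simulate(
    net: Network,
    init: State,
    spec: HybridSpec | None = None,
    gate: str = "clock",
    max_steps: int = 1000,
    markers: tuple[str, ...] | None = None,
) -> tuple[Trajectory, HybridTrace, int | None]:
    """Run the discrete network in lockstep with the continuous switch.

    At each discrete time t the hybrid node's value is set to the
    discretization of c(t) before the synchronous update.  Gating modes:

    * ``"clock"`` (default): the decay clock runs from simulation start, so
      the switch fires at the fixed half-decay time t_d.
    * ``"ctla4"``: c(t) is held at 1 until the CTLA4dim node first becomes
      active; the decay clock starts at that moment (shutdown cannot precede
      checkpoint engagement).

    Returns (trajectory, trace, t_ac) where t_ac is the first step at which
    all activation-marker nodes are simultaneously active (None if never).
    The run converges when the discrete system reaches a fixed point under a
    hybrid value that can no longer change.  A post-hoc warning is emitted if
    the measured t_ac violates t_d >= t_ac (the core would be shut down
    before it is fully expressed).
    """
    if net.hybrid is None:
        raise HybridConfigError("network has no declared hybrid node")
    spec = spec or HybridSpec()
    markers = markers or tuple(m for m in ACTIVATION_MARKERS if m in net.names)
    net.validate_state(init)
    gate_node = "CTLA4dim" if "CTLA4dim" in net.names else None
    if gate not in ("clock", "ctla4"):
        raise ValueError(f"unknown gate mode {gate!r}")
    if gate == "ctla4" and gate_node is None:
        raise HybridConfigError("ctla4-gated mode requires a CTLA4dim node")

    cur = {n: (1 if init[n] else 0) for n in net.names}
    traj = Trajectory(states=[], update_scheme="hybrid-sync")
    trace = HybridTrace()
    t_ac: int | None = None
    clock_started = gate == "clock"
    clock_offset = 0

    for t in range(max_steps + 1):
        if gate == "ctla4" and not clock_started and cur[gate_node]:
            clock_started = True
            clock_offset = t
        c = logistic_value(t - clock_offset, spec) if clock_started else 1.0
        d = discretize(c, spec.theta)
        cur[net.hybrid] = d
        trace.times.append(t)
        trace.cd8086_continuous.append(c)
        trace.cd8086_discrete.append(d)
        traj.states.append(dict(cur))
        if t_ac is None and markers and all(cur[m] for m in markers):
            t_ac = t
        nxt = step_sync(net, cur)
        # The run has converged only if the discrete state is fixed AND the
        # hybrid value can never change again: once the decay clock runs the
        # capacity is monotone decreasing, so the value is settled when it has
        # reached 0 (or the decay is disabled); before the clock starts
        # (ctla4 gate) it is settled if the fixed state keeps the gate shut.
        if clock_started:
            hybrid_settled = d == 0 or math.isinf(spec.t_d)
        else:
            hybrid_settled = not nxt[gate_node]
        if nxt == cur and hybrid_settled:
            traj.converged = True
            traj.steps_to_attractor = t
            break
        cur = nxt

    if t_ac is not None and spec.t_d < t_ac:
        warnings.warn(
            f"half-decay time t_d={spec.t_d} is shorter than the measured "
            f"activation-completion time t_ac={t_ac}; the activation core is "
            "shut down before it is fully expressed",
            stacklevel=2,
        )
    return traj, trace, t_ac
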