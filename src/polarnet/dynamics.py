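"""Synchronous threshold dynamics and attractor detection.

The state of the network advances deterministically by

    S(t+1) = thr(W . S(t) - theta_eff),    thr(x) = 1 iff x >= 0,

where ``theta_eff`` is the threshold vector after environment clamping and
perturbation overrides.  Clamping works purely through thresholds: an input
held active gets threshold 0 (``thr(0) = 1`` with no incoming edges), an
input held inactive — and any inhibited node — gets an unreachably large
threshold ``B = 1 + sum(|W|)``; a constitutively activated node gets ``-B``.

Every run starts from the all-inactive state at step 0; clamped inputs
switch on at step 1.  The trajectory of a finite deterministic system is
eventually periodic, and the attractor (minimal cycle plus exact transient
length) is recovered with Brent's power-of-two cycle-detection algorithm,
which needs only O(1) stored states.

Weights and thresholds are small binary fractions (multiples of 0.5), so
the ``>= 0`` comparison inside ``thr`` is exact in floating point; no
tolerance is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .network_io import BooleanControlNetwork


class NonConvergenceError(RuntimeError):
    """Cycle not confirmed within the step budget."""

    def __init__(self, steps: int, context: str = ""):
        self.steps = steps
        msg = f"no attractor confirmed within {steps} steps"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


@dataclass(frozen=True)
class Environment:
    """Fixed on/off assignment of the input nodes for one run.

    ``active_inputs`` lists the input nodes clamped active; all other
    inputs are clamped inactive.
    """

    active_inputs: frozenset[str]

    def __init__(self, active_inputs: Iterable[str] = ()):
        object.__setattr__(self, "active_inputs", frozenset(active_inputs))

    def validate(self, net: BooleanControlNetwork) -> None:
        inputs = set(net.input_ids)
        bad = self.active_inputs - inputs
        if bad:
            raise ValueError(f"not input-class node(s): {sorted(bad)}")

    def bitmask(self, net: BooleanControlNetwork) -> int:
        """Integer mask, bit j set iff the j-th input (node-table order) is active."""
        mask = 0
        for j, nid in enumerate(net.input_ids):
            if nid in self.active_inputs:
                mask |= 1 << j
        return mask

    def label(self) -> str:
        return "+".join(sorted(self.active_inputs)) or "(none)"


@dataclass(frozen=True)
class Perturbation:
    """Nodes forced inactive (``inhibited``) or active (``activated``).

    Perturbations model 100%-efficient interventions realized as threshold
    overrides; the two sets must be disjoint.  By default only inner nodes
    may be perturbed (inputs are the environment's business and outputs are
    readouts); pass ``allow_boundary=True`` to the dynamics functions to
    lift that restriction.
    """

    inhibited: frozenset[str] = frozenset()
    activated: frozenset[str] = frozenset()

    def __init__(self, inhibited: Iterable[str] = (), activated: Iterable[str] = ()):
        object.__setattr__(self, "inhibited", frozenset(inhibited))
        object.__setattr__(self, "activated", frozenset(activated))

    def validate(self, net: BooleanControlNetwork, allow_boundary: bool = False) -> None:
        overlap = self.inhibited & self.activated
        if overlap:
            raise ValueError(f"node(s) both inhibited and activated: {sorted(overlap)}")
        for nid in self.inhibited | self.activated:
            if nid not in net.index:
                raise ValueError(f"unknown node {nid!r}")
            if not allow_boundary and net.node(nid).klass != "inner":
                raise ValueError(
                    f"{nid!r} is {net.node(nid).klass}-class; perturb inner nodes only "
                    "(or pass allow_boundary=True)"
                )

    def label(self) -> str:
        parts = [f"-{n}" for n in sorted(self.inhibited)]
        parts += [f"+{n}" for n in sorted(self.activated)]
        return ",".join(parts) or "(none)"


NO_PERTURBATION = Perturbation()


@dataclass(frozen=True)
class Attractor:
    """Result of one run: exact transient plus minimal state cycle.

    ``cycle`` is a (period, n) binary array; applying one synchronous step
    to row k yields row (k+1) mod period.  ``activity[j]`` is the fraction
    of cycle states in which node j is active — the quantity the
    polarization index is computed from.  A steady state has period 1 and
    0/1 activities.
    """

    transient_length: int
    cycle: np.ndarray
    activity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        cyc = np.asarray(self.cycle, dtype=np.uint8)
        if cyc.ndim != 2:
            raise ValueError("cycle must be a (period, n) array")
        object.__setattr__(self, "cycle", cyc)
        object.__setattr__(self, "activity", cyc.mean(axis=0))

    @property
    def period(self) -> int:
        return self.cycle.shape[0]

    @property
    def is_steady_state(self) -> bool:
        return self.period == 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Attractor):
            return NotImplemented
        return (
            self.transient_length == other.transient_length
            and self.cycle.shape == other.cycle.shape
            and bool(np.array_equal(self.cycle, other.cycle))
        )


def threshold_function(x):
    """Heaviside-style activation: 1 iff ``x >= 0`` (elementwise on arrays)."""
    return (np.asarray(x) >= 0).astype(np.uint8) if np.ndim(x) else np.uint8(x >= 0)


def unreachable_bound(net: BooleanControlNetwork) -> float:
    """A threshold shift no weighted input sum can overcome: 1 + sum(|W|)."""
    return 1.0 + float(np.abs(net.W).sum())


def effective_thresholds(
    net: BooleanControlNetwork,
    env: Environment | None = None,
    pert: Perturbation | None = None,
    allow_boundary: bool = False,
) -> np.ndarray:
    """Threshold vector after clamping and perturbation overrides.

    Active inputs get 0, inactive inputs +B, inhibited nodes +B, activated
    nodes -B, with B unreachable by any weighted input sum.  Perturbation
    overrides are applied last and win over the environment.
    """
    env = env if env is not None else Environment()
    pert = pert if pert is not None else NO_PERTURBATION
    env.validate(net)
    pert.validate(net, allow_boundary=allow_boundary)
    theta = net.theta.copy()
    bound = unreachable_bound(net)
    for nid in net.input_ids:
        theta[net.index[nid]] = 0.0 if nid in env.active_inputs else bound
    for nid in pert.inhibited:
        theta[net.index[nid]] = bound
    for nid in pert.activated:
        theta[net.index[nid]] = -bound
    return theta


def step(
    net: BooleanControlNetwork,
    state: np.ndarray,
    theta_eff: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update of the whole network."""
    state = np.asarray(state, dtype=float)
    if state.shape[0] != net.n:
        raise ValueError(f"state length {state.shape[0]} != node count {net.n}")
    theta = net.theta if theta_eff is None else theta_eff
    if theta.shape[0] != net.n:
        raise ValueError("threshold vector length mismatch")
    return (net.W @ state - theta >= 0).astype(np.uint8)


def _collect_cycle(net, start_state, theta, transient, period):
    s = start_state
    for _ in range(transient):
        s = step(net, s, theta)
    states = np.empty((period, net.n), dtype=np.uint8)
    for k in range(period):
        states[k] = s
        s = step(net, s, theta)
    return states


def find_attractor(
    net: BooleanControlNetwork,
    env: Environment | None = None,
    pert: Perturbation | None = None,
    max_steps: int = 10_000,
    allow_boundary: bool = False,
) -> Attractor:
    """Attractor reached from the all-inactive state, via Brent's algorithm.

    Brent's method races a teleporting tortoise against a hare over
    power-of-two windows to find the minimal period, then replays two
    pointers one period apart to locate the first cycle state, giving the
    exact transient length.  The state space is finite so termination is
    guaranteed; ``max_steps`` only guards against misconfigured fixtures.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    theta = effective_thresholds(net, env, pert, allow_boundary=allow_boundary)
    start = np.zeros(net.n, dtype=np.uint8)

    evals = 0

    def advance(s):
        nonlocal evals
        evals += 1
        if evals > max_steps:
            raise NonConvergenceError(max_steps)
        return step(net, s, theta)

    # phase 1: minimal period lam
    power = lam = 1
    tortoise = start
    hare = advance(start)
    while not np.array_equal(tortoise, hare):
        if power == lam:
            tortoise = hare
            power *= 2
            lam = 0
        hare = advance(hare)
        lam += 1
    # phase 2: transient length mu via two pointers lam apart
    hare = start
    for _ in range(lam):
        hare = advance(hare)
    tortoise = start
    mu = 0
    while not np.array_equal(tortoise, hare):
        tortoise = advance(tortoise)
        hare = advance(hare)
        mu += 1
    cycle = _collect_cycle(net, start, theta, mu, lam)
    return Attractor(transient_length=mu, cycle=cycle)


def batch_attractors(
    net: BooleanControlNetwork,
    environments: Sequence[Environment],
    pert: Perturbation | None = None,
    max_steps: int = 10_000,
    allow_boundary: bool = False,
) -> list[Attractor]:
    """Attractors for many environments in one vectorized pass.

    All environments are stepped together as the columns of one state
    matrix; a column that reaches a fixed point is frozen with its exact
    transient.  Columns that are still moving after the vectorized window
    (limit cycles, or unusually long transients) fall back to
    :func:`find_attractor`, so the result is bit-identical to mapping
    :func:`find_attractor` over ``environments`` in order.
    """
    if not environments:
        return []
    m = len(environments)
    thetas = np.empty((net.n, m), dtype=float)
    for k, env in enumerate(environments):
        thetas[:, k] = effective_thresholds(net, env, pert, allow_boundary=allow_boundary)
    S = np.zeros((net.n, m), dtype=float)
    results: list[Attractor | None] = [None] * m
    active = np.ones(m, dtype=bool)
    window = min(max_steps, 4 * net.n + 16)
    for t in range(window):
        if not active.any():
            break
        nxt = (net.W @ S - thetas >= 0).astype(float)
        settled = active & (np.abs(nxt - S).sum(axis=0) == 0)
        for k in np.nonzero(settled)[0]:
            results[k] = Attractor(
                transient_length=t, cycle=S[:, k].astype(np.uint8)[None, :]
            )
        active &= ~settled
        S = nxt
    for k in np.nonzero(active)[0]:
        try:
            results[k] = find_attractor(
                net, environments[k], pert, max_steps=max_steps, allow_boundary=allow_boundary
            )
        except NonConvergenceError as exc:
            raise NonConvergenceError(max_steps, context=f"environment index {k}") from exc
    return results  # type: ignore[return-value]


def serialize_attractor(
    attractor: Attractor,
    net: BooleanControlNetwork,
    env: Environment | None = None,
    pert: Perturbation | None = None,
) -> str:
    """TSV text: header metadata lines, then one (node_id, activity) row per node."""
    env = env if env is not None else Environment()
    pert = pert if pert is not None else NO_PERTURBATION
    lines = [
        f"# period\t{attractor.period}",
        f"# transient\t{attractor.transient_length}",
        f"# env\t{env.label()}",
        f"# pert\t{pert.label()}",
        "node_id\tactivity_fraction",
    ]
    for nd, act in zip(net.nodes, attractor.activity):
        lines.append(f"{nd.id}\t{act:.6g}")
    return "\n".join(lines) + "\n"
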