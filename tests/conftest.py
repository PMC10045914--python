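"""Shared fixtures and independent oracles.

The brute-force attractor oracle records every visited state in a table and
finds the cycle by first repetition — O(transient + period) memory, no
cleverness — and serves as the independent reference for Brent-based
detection.  Random small threshold networks (arbitrary wiring, cycles and
self-loops allowed) exercise the detector far outside the feed-forward
regime of the curated model.
"""

from __future__ import annotations

import numpy as np
import pytest

from polarnet import BooleanControlNetwork, EdgeSpec, Environment, NodeSpec
from polarnet.dynamics import effective_thresholds, step


def brute_force_attractor(net, env=None, pert=None, allow_boundary=False):
    """Reference attractor finder: visited-state table, first repetition.

    Returns (transient_length, cycle) with the cycle ordered from its first
    visited state, matching the convention of ``find_attractor``.
    """
    theta = effective_thresholds(net, env, pert, allow_boundary=allow_boundary)
    s = np.zeros(net.n, dtype=np.uint8)
    seen: dict[bytes, int] = {}
    traj: list[np.ndarray] = []
    t = 0
    while s.tobytes() not in seen:
        seen[s.tobytes()] = t
        traj.append(s)
        s = step(net, s, theta)
        t += 1
    first = seen[s.tobytes()]
    return first, np.array(traj[first:t], dtype=np.uint8)


def random_threshold_net(rng: np.random.Generator, n_max: int = 12) -> BooleanControlNetwork:
    """Arbitrary small signed threshold network (cycles/self-loops allowed)."""
    n = int(rng.integers(2, n_max + 1))
    k_in = int(rng.integers(1, min(3, n - 1) + 1))
    thetas = [-0.5, 0.0, 0.5, 1.0]
    nodes = []
    for i in range(n):
        klass = "input" if i < k_in else "inner"
        thr = 1.0 if klass == "input" else float(rng.choice(thetas))
        nodes.append(NodeSpec(id=f"V{i}", klass=klass, threshold=thr))
    weights = [-1.0, -0.5, 0.5, 1.0]
    edges = []
    pairs = set()
    for i in range(k_in, n):
        for _ in range(int(rng.integers(1, 4))):
            src = int(rng.integers(0, n))
            if (f"V{src}", f"V{i}") in pairs:
                continue
            pairs.add((f"V{src}", f"V{i}"))
            edges.append(EdgeSpec(f"V{src}", f"V{i}", float(rng.choice(weights))))
    return BooleanControlNetwork(nodes, edges)


def random_environment(rng: np.random.Generator, net) -> Environment:
    return Environment(nid for nid in net.input_ids if rng.random() < 0.5)


@pytest.fixture
def and_net():
    from polarnet import make_fixture

    return make_fixture("and_gate")


@pytest.fixture
def ring_net():
    from polarnet import make_fixture

    return make_fixture("ring_oscillator")


@pytest.fixture
def synergy_net():
    from polarnet import make_fixture

    return make_fixture("two_path_synergy")


@pytest.fixture
def period3_net():
    """Two inner nodes wired so the orbit from 00 is 00→01→11→10→01…

    A copies B (edge B→A +1, θ_A = 0.5); B is NAND(A, B) (edges −0.5 from
    both, θ_B = −0.5).  Transient 1, minimal period 3 — derived by direct
    enumeration of the 4-state space.
    """
    nodes = [
        NodeSpec(id="A", klass="inner", threshold=0.5),
        NodeSpec(id="B", klass="inner", threshold=-0.5),
    ]
    edges = [
        EdgeSpec("B", "A", 1.0),
        EdgeSpec("A", "B", -0.5),
        EdgeSpec("B", "B", -0.5),
    ]
    return BooleanControlNetwork(nodes, edges)
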