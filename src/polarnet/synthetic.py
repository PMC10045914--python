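"""Synthetic Boolean control networks: hand-built fixtures and random nets.

The hand-built fixtures are minimal circuits with exactly known attractors
(AND/OR/NOT gates, a chain, a negative-feedback ring oscillator, and a
two-parallel-path net built to exhibit pair synergy).  The random generator
emulates the structural shape of curated signaling networks: a three-layer
input → inner → output architecture, weights from {±1, ±0.5} encoding
OR/AND/NOT gates, a mostly feed-forward wiring with optional injected
back-edges, and preferential attachment so inner-node degrees are roughly
power-law distributed.

Randomness comes from ``numpy.random.default_rng`` (PCG64); the same seed
always yields the same network, byte-identical after TSV export.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .network_io import BooleanControlNetwork, EdgeSpec, NodeSpec, export_network

FIXTURE_NAMES = (
    "and_gate",
    "or_gate",
    "not_gate",
    "chain",
    "ring_oscillator",
    "two_path_synergy",
)


@dataclass(frozen=True)
class SynthConfig:
    """Random-network parameters.

    n_in / n_inner / n_out
        Layer sizes (defaults mirror the curated macrophage model's
        9/75/22 split).
    and_gate_fraction
        Probability an inner/output node is wired as an AND gate (two +0.5
        activators) rather than OR (+1 activators).
    inhibitory_fraction
        Probability a node additionally receives a -1 veto edge.
    cycle_edges
        Number of back-edges injected among inner nodes; 0 keeps the net
        acyclic so every attractor is a steady state.
    """

    n_in: int = 9
    n_inner: int = 75
    n_out: int = 22
    and_gate_fraction: float = 0.25
    inhibitory_fraction: float = 0.15
    cycle_edges: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_in, self.n_inner, self.n_out) < 1:
            raise ValueError("layer sizes must all be >= 1")
        for f in (self.and_gate_fraction, self.inhibitory_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.cycle_edges < 0:
            raise ValueError("cycle_edges must be >= 0")


def _node(nid, klass, polarity="none", threshold=1.0, **kw):
    return NodeSpec(id=nid, name=nid, klass=klass, polarity=polarity, threshold=threshold, **kw)


def make_fixture(name: str) -> BooleanControlNetwork:
    """Return a named hand-built network with documented exact attractors.

    ``and_gate``
        IN1, IN2 → (0.5, 0.5) → AND → OUT_T1; the output fires only when
        both inputs are clamped on.
    ``or_gate``
        Same shape with +1 edges; either input suffices.
    ``not_gate``
        ACT (+1) and INH (-1) converge on one inner node; INH vetoes ACT.
    ``chain``
        IN → M1 → M2 → OUT_T1; steady state, transient = path length.
    ``ring_oscillator``
        Three inner nodes in an all-inhibitory ring with threshold 0 (an
        odd number of negations = net negative feedback): the ring
        alternates between all-on and all-off, period 2, and the type-1
        output tracking one ring node has activity 1/2.
    ``two_path_synergy``
        One input feeds two parallel inner paths, either of which alone
        activates the type-1 output; only inhibiting BOTH paths changes
        the polarization, so the pair's synI is |ΔpI|/tau by construction.

    Every fixture carries one type-1 and one type-2 output so the
    polarization index is defined; the type-2 output is held off through an
    inhibitory edge unless stated otherwise.
    """
    if name == "and_gate" or name == "or_gate":
        w = 0.5 if name == "and_gate" else 1.0
        nodes = [
            _node("IN1", "input"),
            _node("IN2", "input"),
            _node("GATE", "inner"),
            _node("OUT_T1", "output", polarity="type1"),
            _node("OUT_T2", "output", polarity="type2"),
        ]
        edges = [
            EdgeSpec("IN1", "GATE", w),
            EdgeSpec("IN2", "GATE", w),
            EdgeSpec("GATE", "OUT_T1", 1.0),
            EdgeSpec("GATE", "OUT_T2", -1.0),
        ]
    elif name == "not_gate":
        nodes = [
            _node("ACT", "input"),
            _node("INH", "input"),
            _node("C", "inner"),
            _node("OUT_T1", "output", polarity="type1"),
            _node("OUT_T2", "output", polarity="type2"),
        ]
        edges = [
            EdgeSpec("ACT", "C", 1.0),
            EdgeSpec("INH", "C", -1.0),
            EdgeSpec("C", "OUT_T1", 1.0),
            EdgeSpec("C", "OUT_T2", -1.0),
        ]
    elif name == "chain":
        nodes = [
            _node("IN", "input"),
            _node("M1", "inner"),
            _node("M2", "inner"),
            _node("OUT_T1", "output", polarity="type1"),
            _node("OUT_T2", "output", polarity="type2"),
        ]
        edges = [
            EdgeSpec("IN", "M1", 1.0),
            EdgeSpec("M1", "M2", 1.0),
            EdgeSpec("M2", "OUT_T1", 1.0),
            EdgeSpec("M2", "OUT_T2", -1.0),
        ]
    elif name == "ring_oscillator":
        nodes = [
            _node("TRIG", "input"),
            _node("R1", "inner", threshold=0.0),
            _node("R2", "inner", threshold=0.0),
            _node("R3", "inner", threshold=0.0),
            _node("OUT_T1", "output", polarity="type1"),
            _node("OUT_T2", "output", polarity="type2"),
        ]
        edges = [
            EdgeSpec("TRIG", "R1", 0.5),
            EdgeSpec("R1", "R2", -1.0),
            EdgeSpec("R2", "R3", -1.0),
            EdgeSpec("R3", "R1", -1.0),
            EdgeSpec("R1", "OUT_T1", 1.0),
            EdgeSpec("R1", "OUT_T2", -1.0),
        ]
    elif name == "two_path_synergy":
        nodes = [
            _node("IN", "input"),
            _node("P1", "inner"),
            _node("P2", "inner"),
            _node("OUT_T1", "output", polarity="type1"),
            _node("OUT_T2", "output", polarity="type2"),
        ]
        edges = [
            EdgeSpec("IN", "P1", 1.0),
            EdgeSpec("IN", "P2", 1.0),
            EdgeSpec("P1", "OUT_T1", 1.0),
            EdgeSpec("P2", "OUT_T1", 1.0),
            EdgeSpec("P1", "OUT_T2", -1.0),
        ]
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    return BooleanControlNetwork(nodes, edges)


def _pick(rng, candidates, out_degree, k):
    """k distinct candidates, preferential by (1 + out-degree)."""
    weights = np.array([1.0 + out_degree[c] for c in candidates])
    p = weights / weights.sum()
    chosen = rng.choice(len(candidates), size=k, replace=False, p=p)
    return [candidates[i] for i in chosen]


def generate_random_bcn(config: SynthConfig) -> BooleanControlNetwork:
    """Generate a layered random network per ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    in_ids = [f"IN{i:02d}" for i in range(config.n_in)]
    inner_ids = [f"N{i:03d}" for i in range(config.n_inner)]
    out_ids = [f"OUT{i:02d}" for i in range(config.n_out)]
    # inputs get alternating polarity too: stimuli are themselves classed as
    # inflammatory or tissue-protective, which the input-layer pI reads
    nodes = [
        _node(i, "input", polarity="type1" if k % 2 == 0 else "type2")
        for k, i in enumerate(in_ids)
    ]
    nodes += [_node(i, "inner") for i in inner_ids]
    nodes += [
        _node(i, "output", polarity="type1" if k % 2 == 0 else "type2")
        for k, i in enumerate(out_ids)
    ]
    edges: list[EdgeSpec] = []
    pairs: set[tuple[str, str]] = set()
    out_degree: dict[str, int] = {nid: 0 for nid in in_ids + inner_ids}

    def add_edge(src, dst, w):
        if (src, dst) in pairs:
            return False
        pairs.add((src, dst))
        edges.append(EdgeSpec(src, dst, w))
        out_degree[src] += 1
        return True

    def wire_node(nid, candidates):
        is_and = len(candidates) >= 2 and rng.random() < config.and_gate_fraction
        if is_and:
            for src in _pick(rng, candidates, out_degree, 2):
                add_edge(src, nid, 0.5)
        else:
            n_src = 2 if (len(candidates) >= 2 and rng.random() < 0.5) else 1
            for src in _pick(rng, candidates, out_degree, n_src):
                add_edge(src, nid, 1.0)
        if rng.random() < config.inhibitory_fraction:
            free = [c for c in candidates if (c, nid) not in pairs]
            if free:
                add_edge(_pick(rng, free, out_degree, 1)[0], nid, -1.0)

    for k, nid in enumerate(inner_ids):
        wire_node(nid, in_ids + inner_ids[:k])
    for nid in out_ids:
        wire_node(nid, inner_ids)

    if config.cycle_edges and config.n_inner >= 2:
        placed = 0
        attempts = 0
        while placed < config.cycle_edges and attempts < 100 * config.cycle_edges:
            attempts += 1
            j, i = sorted(rng.choice(config.n_inner, size=2, replace=False))
            w = -1.0 if rng.random() < config.inhibitory_fraction else 1.0
            if add_edge(inner_ids[i], inner_ids[j], w):  # back-edge: later -> earlier
                placed += 1
    return BooleanControlNetwork(nodes, edges)


def export_synthetic(
    net: BooleanControlNetwork, config: SynthConfig, dest: str | Path
) -> list[Path]:
    """Write nodes.tsv/edges.tsv plus a sidecar metadata file (config + RNG)."""
    dest = Path(dest)
    files = export_network(net, dest, "tsv")
    meta = dest / "synthetic_meta.json"
    meta.write_text(
        json.dumps({"generator": "numpy.random.default_rng (PCG64)", "config": asdict(config)},
                   indent=2)
        + "\n"
    )
    return files + [meta]
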