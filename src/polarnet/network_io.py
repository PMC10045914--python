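"""Network data model and interchange formats.

A :class:`BooleanControlNetwork` is a static description of the signaling
model: an ordered node list, a list of signed weighted edges, the dense
weight matrix ``W`` (row = target, column = source, so ``W @ S`` sums the
incoming weights of each node) and the per-node threshold vector ``theta``.

The canonical on-disk form is a pair of TSV tables:

``nodes.tsv``
    id, name, class{input|inner|output}, is_receptor{0|1}, is_technical{0|1},
    is_constitutive{0|1}, polarity{type1|type2|none}, threshold (float;
    blank = 1.0, or 0.0 for constitutive nodes).

``edges.tsv``
    source, target, weight (float, nonzero), evidence (semicolon-separated
    PubMed IDs, may be blank).

An ``.xlsx`` workbook with sheets named ``nodes`` and ``edges`` holding the
same columns is accepted as a convenience for supplementary spreadsheets.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

NodeClass = Literal["input", "inner", "output"]
Polarity = Literal["type1", "type2", "none"]

_NODE_COLUMNS = [
    "id",
    "name",
    "class",
    "is_receptor",
    "is_technical",
    "is_constitutive",
    "polarity",
    "threshold",
]
_EDGE_COLUMNS = ["source", "target", "weight", "evidence"]


class NetworkLoadError(ValueError):
    """Raised when node/edge tables cannot be assembled into a valid network."""


@dataclass(frozen=True)
class NodeSpec:
    """One node of the network.

    Parameters
    ----------
    id:
        Short unique symbol, e.g. ``"STAT6"``.  Unicode symbols are expected
        to be stored as ASCII aliases (``IFNB`` for IFNβ) with the display
        form in ``name``.
    klass:
        ``input`` (extracellular stimulus, clamped per run), ``inner``
        (signal transducer) or ``output`` (transcriptional readout).
    is_receptor:
        Receptor flag; receptors are normally excluded from inhibition
        screens.
    is_technical:
        Complexes or alternative states represented as separate nodes for
        technical reasons.
    is_constitutive:
        Active with no incoming edges (e.g. JAKs); the default threshold for
        such nodes is 0 so that ``thr(0) = 1`` keeps them on.
    polarity:
        ``type1`` (inflammatory, M1-like) or ``type2`` (tissue-protective,
        M2-like); only meaningful for input and output nodes.
    threshold:
        Per-node activation threshold (entry of ``theta``).
    """

    id: str
    name: str = ""
    klass: NodeClass = "inner"
    is_receptor: bool = False
    is_technical: bool = False
    is_constitutive: bool = False
    polarity: Polarity = "none"
    threshold: float = 1.0


@dataclass(frozen=True)
class EdgeSpec:
    """A signed, weighted directed interaction.

    ``weight > 0`` is stimulatory, ``weight < 0`` inhibitory.  Canonical
    magnitudes are 1.0 (sufficient alone, OR semantics) and 0.5 (two such
    edges jointly necessary, AND semantics).
    """

    source: str
    target: str
    weight: float
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class Violation:
    """One validation rule breach; ``subject`` names the node or edge."""

    rule: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.subject}: {self.message}"


class BooleanControlNetwork:
    """Static model: nodes, edges, weight matrix and thresholds.

    Attributes
    ----------
    nodes : list[NodeSpec]
        Ordered node list; all matrices/vectors follow this order.
    edges : list[EdgeSpec]
        Edge list; ``(source, target)`` pairs are unique.
    W : numpy.ndarray, shape (n, n)
        Signed weight matrix, ``W[i, j]`` = weight of edge j -> i.
    theta : numpy.ndarray, shape (n,)
        Threshold vector.
    index : dict[str, int]
        Node id to position.
    """

    def __init__(self, nodes: Sequence[NodeSpec], edges: Sequence[EdgeSpec]):
        self.nodes: list[NodeSpec] = list(nodes)
        self.edges: list[EdgeSpec] = list(edges)
        ids = [nd.id for nd in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkLoadError(f"duplicate node id(s): {', '.join(dupes)}")
        self.index: dict[str, int] = {nd.id: k for k, nd in enumerate(self.nodes)}
        n = len(self.nodes)
        self.W = np.zeros((n, n), dtype=float)
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.index:
                    raise NetworkLoadError(
                        f"edge {e.source}->{e.target} references unknown node {endpoint!r}"
                    )
            if (e.source, e.target) in seen_pairs:
                raise NetworkLoadError(f"duplicate edge {e.source}->{e.target}")
            seen_pairs.add((e.source, e.target))
            if e.weight == 0 or not math.isfinite(e.weight):
                raise NetworkLoadError(
                    f"edge {e.source}->{e.target} has invalid weight {e.weight!r}"
                )
            self.W[self.index[e.target], self.index[e.source]] = e.weight
        self.theta = np.array([nd.threshold for nd in self.nodes], dtype=float)

    # -- convenience views -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    def ids(self) -> list[str]:
        return [nd.id for nd in self.nodes]

    def nodes_of_class(self, klass: NodeClass) -> list[NodeSpec]:
        return [nd for nd in self.nodes if nd.klass == klass]

    @property
    def input_ids(self) -> list[str]:
        return [nd.id for nd in self.nodes if nd.klass == "input"]

    @property
    def inner_ids(self) -> list[str]:
        return [nd.id for nd in self.nodes if nd.klass == "inner"]

    @property
    def output_ids(self) -> list[str]:
        return [nd.id for nd in self.nodes if nd.klass == "output"]

    def class_counts(self) -> dict[str, int]:
        return {
            "input": len(self.input_ids),
            "inner": len(self.inner_ids),
            "output": len(self.output_ids),
        }

    def node(self, node_id: str) -> NodeSpec:
        return self.nodes[self.index[node_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanControlNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: (e.source, e.target))
            == sorted(other.edges, key=lambda e: (e.source, e.target))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        c = self.class_counts()
        return (
            f"BooleanControlNetwork(n={self.n} "
            f"[{c['input']} in/{c['inner']} inner/{c['output']} out], "
            f"edges={len(self.edges)})"
        )


# ---------------------------------------------------------------------------
# loading


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    s = str(value).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"", "0", "false", "no", "nan"}:
        return False
    raise NetworkLoadError(f"cannot interpret {value!r} as a 0/1 flag")


def _node_from_row(row: pd.Series) -> NodeSpec:
    klass = str(row["class"]).strip()
    if klass not in ("input", "inner", "output"):
        raise NetworkLoadError(f"node {row['id']!r}: unknown class {klass!r}")
    polarity = str(row.get("polarity", "none") or "none").strip() or "none"
    if polarity not in ("type1", "type2", "none"):
        raise NetworkLoadError(f"node {row['id']!r}: unknown polarity {polarity!r}")
    constitutive = _parse_bool(row.get("is_constitutive", 0))
    raw_thr = row.get("threshold", None)
    if raw_thr is None or (isinstance(raw_thr, float) and math.isnan(raw_thr)) or str(raw_thr).strip() == "":
        threshold = 0.0 if constitutive else 1.0
    else:
        threshold = float(raw_thr)
    name = row.get("name", "")
    if name is None or (isinstance(name, float) and math.isnan(name)):
        name = ""
    return NodeSpec(
        id=str(row["id"]).strip(),
        name=str(name),
        klass=klass,  # type: ignore[arg-type]
        is_receptor=_parse_bool(row.get("is_receptor", 0)),
        is_technical=_parse_bool(row.get("is_technical", 0)),
        is_constitutive=constitutive,
        polarity=polarity,  # type: ignore[arg-type]
        threshold=threshold,
    )


def _edge_from_row(row: pd.Series) -> EdgeSpec:
    raw_ev = row.get("evidence", "")
    if raw_ev is None or (isinstance(raw_ev, float) and math.isnan(raw_ev)):
        raw_ev = ""
    evidence = tuple(p.strip() for p in str(raw_ev).split(";") if p.strip())
    try:
        weight = float(row["weight"])
    except (TypeError, ValueError) as exc:
        raise NetworkLoadError(
            f"edge {row['source']}->{row['target']}: bad weight {row['weight']!r}"
        ) from exc
    return EdgeSpec(
        source=str(row["source"]).strip(),
        target=str(row["target"]).strip(),
        weight=weight,
        evidence=evidence,
    )


def _read_table(path: Path, sheet: str) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet, dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])


def load_network(nodes_table: str | Path, edges_table: str | Path | None = None) -> BooleanControlNetwork:
    """Load a network from the canonical TSV pair (or an xlsx workbook).

    ``nodes_table``/``edges_table`` are paths to TSV files.  If
    ``nodes_table`` points to an ``.xlsx`` workbook and ``edges_table`` is
    omitted, sheets named ``nodes`` and ``edges`` are used.

    Raises
    ------
    NetworkLoadError
        On unknown node ids in edges, duplicate edges, zero weights, or
        malformed columns.
    """
    nodes_path = Path(nodes_table)
    if edges_table is None:
        if nodes_path.suffix.lower() not in (".xlsx", ".xls"):
            raise NetworkLoadError("edges_table required unless loading an xlsx workbook")
        edges_path = nodes_path
    else:
        edges_path = Path(edges_table)
    nodes_df = _read_table(nodes_path, "nodes")
    edges_df = _read_table(edges_path, "edges")
    missing = [c for c in ("id", "class") if c not in nodes_df.columns]
    if missing:
        raise NetworkLoadError(f"nodes table missing column(s): {missing}")
    missing = [c for c in ("source", "target", "weight") if c not in edges_df.columns]
    if missing:
        raise NetworkLoadError(f"edges table missing column(s): {missing}")
    nodes = [_node_from_row(row) for _, row in nodes_df.iterrows()]
    edges = [_edge_from_row(row) for _, row in edges_df.iterrows()]
    return BooleanControlNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# validation


def validate_network(net: BooleanControlNetwork) -> list[Violation]:
    """Check all structural invariants; returns violations (empty = valid).

    Violations are data, not exceptions: a loaded-but-inconsistent network
    (e.g. a matrix entry edited post hoc) is reported rule by rule.
    """
    out: list[Violation] = []
    incoming: dict[str, int] = {nd.id: 0 for nd in net.nodes}
    outgoing: dict[str, int] = {nd.id: 0 for nd in net.nodes}
    for e in net.edges:
        incoming[e.target] += 1
        outgoing[e.source] += 1
        if e.weight == 0:
            out.append(Violation("zero-weight edge", f"{e.source}->{e.target}", "weight is 0"))
    for nd in net.nodes:
        if nd.klass not in ("input", "inner", "output"):
            out.append(Violation("unknown class", nd.id, f"class {nd.klass!r}"))
        if nd.polarity != "none" and nd.klass == "inner":
            out.append(
                Violation(
                    "polarity on inner node",
                    nd.id,
                    "polarity is only meaningful for input/output nodes",
                )
            )
        if nd.is_constitutive and incoming[nd.id] > 0:
            out.append(
                Violation(
                    "constitutive with inputs",
                    nd.id,
                    f"flagged constitutive but has {incoming[nd.id]} incoming edge(s)",
                )
            )
        if nd.klass == "input" and incoming[nd.id] > 0:
            out.append(
                Violation("input with incoming edges", nd.id, f"{incoming[nd.id]} incoming edge(s)")
            )
        if (
            nd.klass == "output"
            and outgoing[nd.id] > 0
            and not (nd.is_technical or nd.is_constitutive)
        ):
            out.append(
                Violation("output with outgoing edges", nd.id, f"{outgoing[nd.id]} outgoing edge(s)")
            )
        if nd.klass == "inner" and incoming[nd.id] == 0 and not nd.is_constitutive:
            out.append(
                Violation(
                    "isolated inner node",
                    nd.id,
                    "no incoming edges and not flagged constitutive",
                )
            )
    # W consistency: nonzero entries must correspond 1:1 to edges
    edge_pairs = {(net.index[e.source], net.index[e.target]) for e in net.edges}
    rows, cols = np.nonzero(net.W)
    for i, j in zip(rows, cols):
        if (j, i) not in edge_pairs:
            out.append(
                Violation(
                    "stray matrix entry",
                    f"{net.nodes[j].id}->{net.nodes[i].id}",
                    f"W[{i},{j}]={net.W[i, j]} without a matching edge",
                )
            )
    for e in net.edges:
        if net.W[net.index[e.target], net.index[e.source]] != e.weight:
            out.append(
                Violation(
                    "matrix/edge mismatch",
                    f"{e.source}->{e.target}",
                    "W entry differs from edge weight",
                )
            )
    if net.theta.shape != (net.n,):
        out.append(Violation("bad theta length", "theta", f"{net.theta.shape} != ({net.n},)"))
    return out


# ---------------------------------------------------------------------------
# export


def nodes_frame(net: BooleanControlNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [nd.id for nd in net.nodes],
            "name": [nd.name for nd in net.nodes],
            "class": [nd.klass for nd in net.nodes],
            "is_receptor": [int(nd.is_receptor) for nd in net.nodes],
            "is_technical": [int(nd.is_technical) for nd in net.nodes],
            "is_constitutive": [int(nd.is_constitutive) for nd in net.nodes],
            "polarity": [nd.polarity for nd in net.nodes],
            "threshold": [repr(nd.threshold) for nd in net.nodes],
        }
    )


def edges_frame(net: BooleanControlNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [e.source for e in net.edges],
            "target": [e.target for e in net.edges],
            "weight": [repr(e.weight) for e in net.edges],
            "evidence": [";".join(e.evidence) for e in net.edges],
        }
    )


def to_networkx(net: BooleanControlNetwork):
    """Directed networkx view with weight/class/polarity node+edge data."""
    import networkx as nx

    g = nx.DiGraph()
    for nd in net.nodes:
        g.add_node(
            nd.id,
            name=nd.name,
            **{"class": nd.klass},
            polarity=nd.polarity,
            threshold=nd.threshold,
        )
    for e in net.edges:
        g.add_edge(e.source, e.target, weight=e.weight)
    return g


def export_network(
    net: BooleanControlNetwork,
    dest: str | Path,
    fmt: Literal["tsv", "sif", "graphml"] = "tsv",
) -> list[Path]:
    """Write the network to ``dest``; returns the file(s) written.

    ``tsv``
        ``dest`` is a directory; writes ``nodes.tsv`` and ``edges.tsv``.
        Round-trips exactly through :func:`load_network` (thresholds and
        weights serialized with ``repr`` so binary fractions survive).
    ``sif``
        One ``source<TAB>activates|inhibits<TAB>target`` line per edge.
    ``graphml``
        Standard GraphML with ``weight`` (double) and ``class`` (string)
        attributes, via networkx.
    """
    dest = Path(dest)
    if fmt == "tsv":
        dest.mkdir(parents=True, exist_ok=True)
        npath, epath = dest / "nodes.tsv", dest / "edges.tsv"
        nodes_frame(net).to_csv(npath, sep="\t", index=False)
        edges_frame(net).to_csv(epath, sep="\t", index=False)
        return [npath, epath]
    if fmt == "sif":
        lines = [
            f"{e.source}\t{'activates' if e.weight > 0 else 'inhibits'}\t{e.target}"
            for e in net.edges
        ]
        dest.write_text("\n".join(lines) + ("\n" if lines else ""))
        return [dest]
    if fmt == "graphml":
        import networkx as nx

        nx.write_graphml(to_networkx(net), dest)
        return [dest]
    raise ValueError(f"unknown export format {fmt!r}")
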