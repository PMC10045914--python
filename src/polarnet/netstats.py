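"""Structural statistics: degree distribution, power-law fit, betweenness.

Degree here is total degree (in + out) on the directed simple graph; signs
and weights are ignored — these statistics are topological.  The power-law
check regresses log(count) on log(degree) over the occupied degree classes
(optionally excluding outlier degrees) and reports the R² of that line
together with the exponent (the negated slope).  Betweenness is standard
directed shortest-path betweenness with the (n-1)(n-2) normalization,
computed via networkx.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network_io import BooleanControlNetwork, to_networkx


@dataclass(frozen=True)
class DegreeDistribution:
    """Map degree value → node count, with the degrees excluded from fits."""

    counts: Mapping[int, int]
    excluded_degrees: frozenset[int] = frozenset()

    def total_nodes(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        degs = sorted(self.counts)
        return pd.DataFrame({"degree": degs, "count": [self.counts[d] for d in degs]})


def degree_distribution(net: BooleanControlNetwork) -> DegreeDistribution:
    """Tally of total (in + out) degree over the directed edge set."""
    deg = Counter({nd.id: 0 for nd in net.nodes})
    for e in net.edges:
        deg[e.source] += 1
        deg[e.target] += 1
    return DegreeDistribution(counts=dict(Counter(deg.values())) if net.nodes else {})


def power_law_fit(
    dist: DegreeDistribution, exclude: Iterable[int] = ()
) -> tuple[float, float]:
    """Least-squares line on log(count) vs log(degree); returns (exponent, R²).

    Degree classes with zero count, degree 0, and the ``exclude`` set are
    left out.  Needs at least 3 usable degree classes.
    """
    excl = set(exclude) | set(dist.excluded_degrees)
    pts = [
        (d, c)
        for d, c in sorted(dist.counts.items())
        if d > 0 and c > 0 and d not in excl
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 usable degree classes, have {len(pts)}")
    x = np.log([d for d, _ in pts])
    y = np.log([c for _, c in pts])
    fit = stats.linregress(x, y)
    return float(-fit.slope), float(fit.rvalue**2)


def betweenness(net: BooleanControlNetwork) -> dict[str, float]:
    """Directed shortest-path betweenness, unweighted, signs ignored.

    Normalized by (n-1)(n-2), the number of ordered node pairs a node could
    mediate.
    """
    import networkx as nx

    g = to_networkx(net)
    return dict(nx.betweenness_centrality(g, normalized=True))


def centrality_frame(net: BooleanControlNetwork) -> pd.DataFrame:
    """Per-node table: id, total degree, betweenness (descending betweenness)."""
    deg = Counter({nd.id: 0 for nd in net.nodes})
    for e in net.edges:
        deg[e.source] += 1
        deg[e.target] += 1
    btw = betweenness(net)
    df = pd.DataFrame(
        {
            "node_id": [nd.id for nd in net.nodes],
            "degree": [deg[nd.id] for nd in net.nodes],
            "betweenness": [btw[nd.id] for nd in net.nodes],
        }
    )
    return df.sort_values("betweenness", ascending=False, kind="stable").reset_index(drop=True)
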