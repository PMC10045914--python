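"""Polarization index and flip detection.

The polarization state of the cell is read off the attractor as

    pI = A1/T1 - A2/T2

where A1 sums the attractor activity fractions of the type-1 (inflammatory,
M1-like) nodes of a layer, A2 those of the type-2 (tissue-protective,
M2-like) nodes, and T1/T2 count the nodes of each type.  pI lies in
[-1, 1]: +1 is a fully M1-like pattern, -1 fully M2-like.  For a limit
cycle the activity fraction of a node is the ratio of cycle states in which
it is active, so pI interpolates continuously.

The index is usually computed over the output layer (transcriptional
readout); the same formula over the input layer scores how inflammatory the
stimulus mix itself is — inputs are constant across the attractor, so their
activity fractions are 0/1.

A perturbation "flips" the polarization when both the baseline and the
perturbed run are committed (|pI| above a threshold, 0.2 by default) and the
two pI values have opposite signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .dynamics import Attractor, Environment, batch_attractors
from .network_io import BooleanControlNetwork


class UndefinedIndexError(ValueError):
    """The chosen layer lacks type-1 or type-2 nodes, so pI is undefined."""


@dataclass(frozen=True)
class PolarizationResult:
    """pI with its components: A1/A2 summed activities, T1/T2 node counts."""

    pI: float
    A1: float
    A2: float
    T1: int
    T2: int


def polarization_index(
    attractor: Attractor,
    net: BooleanControlNetwork,
    layer: Literal["output", "input"] = "output",
) -> PolarizationResult:
    """Polarization index of one attractor over the output or input layer."""
    if layer not in ("output", "input"):
        raise ValueError(f"layer must be 'output' or 'input', got {layer!r}")
    idx1 = [net.index[nd.id] for nd in net.nodes if nd.klass == layer and nd.polarity == "type1"]
    idx2 = [net.index[nd.id] for nd in net.nodes if nd.klass == layer and nd.polarity == "type2"]
    if not idx1 or not idx2:
        raise UndefinedIndexError(
            f"layer {layer!r} needs at least one type1 and one type2 node "
            f"(found T1={len(idx1)}, T2={len(idx2)})"
        )
    a1 = float(attractor.activity[idx1].sum())
    a2 = float(attractor.activity[idx2].sum())
    return PolarizationResult(
        pI=a1 / len(idx1) - a2 / len(idx2), A1=a1, A2=a2, T1=len(idx1), T2=len(idx2)
    )


def detect_flip(pI_base: float, pI_pert: float, threshold: float = 0.2) -> int:
    """1 iff both runs are committed (|pI| > threshold) with opposite signs.

    The inequalities are strict; a pI of exactly 0 is signless and can never
    participate in a flip.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if abs(pI_base) <= threshold or abs(pI_pert) <= threshold:
        return 0
    return int(math.copysign(1.0, pI_base) != math.copysign(1.0, pI_pert))


def input_output_correlation(
    net: BooleanControlNetwork,
    environments: Sequence[Environment],
    max_steps: int = 10_000,
) -> float:
    """Pearson r between input-layer and output-layer pI across environments.

    Unperturbed runs only.  Requires at least 3 environments and nonzero
    variance in both series.
    """
    if len(environments) < 3:
        raise ValueError("need at least 3 environments for a correlation")
    attractors = batch_attractors(net, list(environments), max_steps=max_steps)
    pi_in = [polarization_index(a, net, layer="input").pI for a in attractors]
    pi_out = [polarization_index(a, net, layer="output").pI for a in attractors]
    if np.std(pi_in) == 0 or np.std(pi_out) == 0:
        raise ValueError("zero variance in a pI series; correlation undefined")
    r, _ = stats.pearsonr(pi_in, pi_out)
    return float(r)
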