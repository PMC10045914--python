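"""Exhaustive single- and double-target inhibition screens.

A screen runs the model over every non-empty input combination
("environment") with one target (order 1) or one unordered pair of targets
(order 2) held inactive, mimicking 100%-efficient small-molecule
inhibition.  For each case it records the change in polarization index
ΔpI = pI_perturbed - pI_baseline, whether the case flips an established
polarization, and — for pairs — the synergy index

    synI(A, B, i) = |ΔpI(AB, i)| / max(|ΔpI(A, i)| + |ΔpI(B, i)|, tau)

comparing the pair effect to the sum of the single-target effects under the
same environment i.  The floor tau (default 0.1) prevents runaway ratios
when both single effects are negligible.  synI > 1 is synergy, synI = 1
additivity (independent/parallel pathways), synI < 1 overlap within a
shared pathway.

Eligible targets are the inner nodes, excluding receptors — the
therapeutically conventional exceptions TLR2 and TLR4 stay in.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import pandas as pd

from .dynamics import Environment, Perturbation, batch_attractors
from .network_io import BooleanControlNetwork
from .polarization import detect_flip, polarization_index

#: tolerance for classifying synI as exactly additive (= 1); pI values are
#: ratios of small integers so exact additivity is genuinely representable
ADDITIVE_TOL = 1e-9

#: receptor nodes that remain screenable despite the receptor exclusion
RECEPTOR_EXCEPTIONS = frozenset({"TLR2", "TLR4"})


@dataclass(frozen=True)
class ScreenConfig:
    """Screen parameters.

    tau
        Floor of the synergy-index denominator.
    flip_threshold
        |pI| both runs must exceed (strictly) for a flip; 0.2 matches the
        observed gap between committed and transitory output groups.
    shift_threshold
        |ΔpI| cutoff for counting a case as a notable shift (default 0.4).
    order
        1 = single inhibitions, 2 = unordered pairs.
    """

    tau: float = 0.1
    flip_threshold: float = 0.2
    shift_threshold: float = 0.4
    order: int = 1

    def __post_init__(self):
        if self.tau <= 0 or self.flip_threshold <= 0 or self.shift_threshold <= 0:
            raise ValueError("tau and thresholds must be > 0")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


@dataclass(frozen=True, slots=True)
class ScreenRecord:
    """One (environment, target-set) case of a screen."""

    env: Environment
    targets: tuple[str, ...]
    pI_base: float
    pI_pert: float
    delta_pI: float
    flip: int
    period: int
    synI: Optional[float] = None

    @property
    def flip_direction(self) -> str:
        if not self.flip:
            return "none"
        return "inflammatory" if self.pI_pert > 0 else "tissue_protective"


def enumerate_environments(net: BooleanControlNetwork) -> list[Environment]:
    """All 2^k - 1 non-empty input subsets, in binary-counting order.

    Bit j of the counter corresponds to the j-th input node in node-table
    order; the all-off environment is excluded (an unstimulated cell is not
    a treatment scenario).
    """
    inputs = net.input_ids
    if not inputs:
        raise ValueError("network has no input nodes")
    envs = []
    for mask in range(1, 1 << len(inputs)):
        envs.append(Environment(inputs[j] for j in range(len(inputs)) if mask >> j & 1))
    return envs


def eligible_targets(net: BooleanControlNetwork) -> list[str]:
    """Inner nodes eligible for inhibition: non-receptors plus TLR2/TLR4."""
    return [
        nd.id
        for nd in net.nodes
        if nd.klass == "inner" and (not nd.is_receptor or nd.id in RECEPTOR_EXCEPTIONS)
    ]


def synergy_index(delta_ab: float, delta_a: float, delta_b: float, tau: float = 0.1) -> float:
    """synI = |ΔpI(AB)| / max(|ΔpI(A)| + |ΔpI(B)|, tau)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return abs(delta_ab) / max(abs(delta_a) + abs(delta_b), tau)


def _pi_for(net, environments, pert, max_steps):
    attractors = batch_attractors(net, environments, pert, max_steps=max_steps)
    return (
        [polarization_index(a, net).pI for a in attractors],
        [a.period for a in attractors],
    )


def run_screen(
    net: BooleanControlNetwork,
    config: ScreenConfig = ScreenConfig(),
    targets: Sequence[str] | None = None,
    max_steps: int = 10_000,
) -> list[ScreenRecord]:
    """Run the exhaustive order-1 or order-2 inhibition screen.

    Baseline attractors are computed once per environment and shared across
    targets; for order 2, the order-1 ΔpI values of the same environment
    feed the synergy index.  Record order is canonical: targets (pairs in
    combination order over the target list) outermost, environments in
    binary-counting order innermost.
    """
    if targets is None:
        targets = eligible_targets(net)
    else:
        targets = list(targets)
    envs = enumerate_environments(net)
    base_pi, _ = _pi_for(net, envs, None, max_steps)

    single_pi: dict[str, list[float]] = {}
    single_periods: dict[str, list[int]] = {}
    for t in targets:
        single_pi[t], single_periods[t] = _pi_for(net, envs, Perturbation(inhibited=[t]), max_steps)

    records: list[ScreenRecord] = []
    if config.order == 1:
        for t in targets:
            for k, env in enumerate(envs):
                pi_p = single_pi[t][k]
                records.append(
                    ScreenRecord(
                        env=env,
                        targets=(t,),
                        pI_base=base_pi[k],
                        pI_pert=pi_p,
                        delta_pI=pi_p - base_pi[k],
                        flip=detect_flip(base_pi[k], pi_p, config.flip_threshold),
                        period=single_periods[t][k],
                    )
                )
        return records

    for a, b in combinations(targets, 2):
        pair_pi, pair_periods = _pi_for(net, envs, Perturbation(inhibited=[a, b]), max_steps)
        for k, env in enumerate(envs):
            pi_p = pair_pi[k]
            d_ab = pi_p - base_pi[k]
            records.append(
                ScreenRecord(
                    env=env,
                    targets=(a, b),
                    pI_base=base_pi[k],
                    pI_pert=pi_p,
                    delta_pI=d_ab,
                    flip=detect_flip(base_pi[k], pi_p, config.flip_threshold),
                    period=pair_periods[k],
                    synI=synergy_index(
                        d_ab,
                        single_pi[a][k] - base_pi[k],
                        single_pi[b][k] - base_pi[k],
                        config.tau,
                    ),
                )
            )
    return records


def summarize_screen(records: Sequence[ScreenRecord], config: ScreenConfig = ScreenConfig()) -> dict:
    """Counts and fractions over a screen's records.

    Shifts are |ΔpI| beyond ``config.shift_threshold`` in either direction;
    flips are split by destination polarization; limit cycles are cases
    whose perturbed attractor has period > 1.  For pair screens the synI
    distribution is bucketed into <1 / =1 / >1 (additivity tolerance
    ``ADDITIVE_TOL``) and the share of flips each node participates in is
    tabulated per flip direction.  Percentages are rounded to 2 decimals.
    """
    if not records:
        raise ValueError("empty record list")
    n = len(records)
    s = config.shift_threshold
    shift_up = sum(1 for r in records if r.delta_pI > s)
    shift_down = sum(1 for r in records if r.delta_pI < -s)
    flips_inf = sum(1 for r in records if r.flip_direction == "inflammatory")
    flips_tp = sum(1 for r in records if r.flip_direction == "tissue_protective")
    limit_cycles = sum(1 for r in records if r.period > 1)

    def pct(x: int) -> float:
        return round(100.0 * x / n, 2)

    summary: dict = {
        "n_cases": n,
        "shift_up_count": shift_up,
        "shift_up_pct": pct(shift_up),
        "shift_down_count": shift_down,
        "shift_down_pct": pct(shift_down),
        "flips_toward_inflammation": flips_inf,
        "flips_toward_tissue_protection": flips_tp,
        "limit_cycle_count": limit_cycles,
        "limit_cycle_pct": pct(limit_cycles),
    }
    has_syn = any(r.synI is not None for r in records)
    if has_syn:
        syn = [r.synI for r in records if r.synI is not None]
        n_syn = len(syn)
        additive = sum(1 for v in syn if abs(v - 1.0) <= ADDITIVE_TOL)
        below = sum(1 for v in syn if v < 1.0 - ADDITIVE_TOL)
        above = n_syn - additive - below
        summary.update(
            {
                "synI_below_1_count": below,
                "synI_below_1_pct": round(100.0 * below / n_syn, 2),
                "synI_equal_1_count": additive,
                "synI_equal_1_pct": round(100.0 * additive / n_syn, 2),
                "synI_above_1_count": above,
                "synI_above_1_pct": round(100.0 * above / n_syn, 2),
            }
        )
        for direction, key in (
            ("inflammatory", "flip_involvement_inflammatory"),
            ("tissue_protective", "flip_involvement_tissue_protective"),
        ):
            flips = [r for r in records if r.flip_direction == direction]
            involvement: dict[str, float] = {}
            if flips:
                for node in sorted({t for r in flips for t in r.targets}):
                    involvement[node] = round(
                        100.0 * sum(1 for r in flips if node in r.targets) / len(flips), 2
                    )
            summary[key] = involvement
    return summary


def records_to_frame(records: Sequence[ScreenRecord], net: BooleanControlNetwork) -> pd.DataFrame:
    """Flat table of screen records (the TSV export schema)."""
    return pd.DataFrame(
        {
            "env_bitmask": [r.env.bitmask(net) for r in records],
            "env_ids": [r.env.label() for r in records],
            "target1": [r.targets[0] for r in records],
            "target2": [r.targets[1] if len(r.targets) > 1 else "" for r in records],
            "pI_base": [r.pI_base for r in records],
            "pI_pert": [r.pI_pert for r in records],
            "delta_pI": [r.delta_pI for r in records],
            "period": [r.period for r in records],
            "flip": [r.flip for r in records],
            "flip_direction": [r.flip_direction for r in records],
            "synI": [("" if r.synI is None else r.synI) for r in records],
        }
    )


def summary_to_text(summary: dict) -> str:
    """Human-readable rendering of :func:`summarize_screen` output."""
    lines = [f"cases: {summary['n_cases']}"]
    lines.append(
        f"shift > +threshold: {summary['shift_up_count']} ({summary['shift_up_pct']}%)"
    )
    lines.append(
        f"shift < -threshold: {summary['shift_down_count']} ({summary['shift_down_pct']}%)"
    )
    lines.append(f"flips toward inflammation: {summary['flips_toward_inflammation']}")
    lines.append(f"flips toward tissue protection: {summary['flips_toward_tissue_protection']}")
    lines.append(
        f"limit cycles: {summary['limit_cycle_count']} ({summary['limit_cycle_pct']}%)"
    )
    if "synI_equal_1_count" in summary:
        lines.append(
            "synI buckets: "
            f"<1: {summary['synI_below_1_count']} ({summary['synI_below_1_pct']}%), "
            f"=1: {summary['synI_equal_1_count']} ({summary['synI_equal_1_pct']}%), "
            f">1: {summary['synI_above_1_count']} ({summary['synI_above_1_pct']}%)"
        )
        for key, title in (
            ("flip_involvement_inflammatory", "flip involvement (inflammatory)"),
            ("flip_involvement_tissue_protective", "flip involvement (tissue protective)"),
        ):
            if summary.get(key):
                items = ", ".join(f"{k}: {v}%" for k, v in summary[key].items())
                lines.append(f"{title}: {items}")
    return "\n".join(lines) + "\n"


def summary_to_kv_frame(summary: dict) -> pd.DataFrame:
    """Flat key→value table of a summary (nested dicts dotted)."""
    rows = []
    for k, v in summary.items():
        if isinstance(v, dict):
            for k2, v2 in v.items():
                rows.append((f"{k}.{k2}", v2))
        else:
            rows.append((k, v))
    return pd.DataFrame(rows, columns=["key", "value"])
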