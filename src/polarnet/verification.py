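"""Literature-criteria verification harness.

Published experiments mostly report how a lone extracellular stimulus
changes the expression of a single gene.  Each such report becomes a
criterion: with only ``input_id`` clamped active and no perturbation, the
model's attractor should show ``output_id`` active (or inactive).  The
model is Boolean, so up-/down-regulation maps to active/inactive at the
attractor; for limit cycles an activity fraction >= 0.5 counts as active.

Criteria live in a TSV with columns ``input_id``, ``output_id``,
``expected{active|inactive}``, ``evidence`` (semicolon-separated PubMed
IDs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .dynamics import Environment, batch_attractors
from .network_io import BooleanControlNetwork


@dataclass(frozen=True)
class VerificationCriterion:
    """One single-input → single-output expectation."""

    input_id: str
    output_id: str
    expected: str  # "active" | "inactive"
    evidence: tuple[str, ...] = ()

    def __post_init__(self):
        if self.expected not in ("active", "inactive"):
            raise ValueError(f"expected must be active|inactive, got {self.expected!r}")


@dataclass(frozen=True)
class CriterionResult:
    criterion: VerificationCriterion
    observed_activity: float
    passed: bool


@dataclass(frozen=True)
class VerificationReport:
    results: tuple[CriterionResult, ...]

    @property
    def n_criteria(self) -> int:
        return len(self.results)

    @property
    def n_passed(self) -> int:
        return sum(1 for r in self.results if r.passed)

    @property
    def score(self) -> float:
        """Fraction of criteria satisfied."""
        return self.n_passed / self.n_criteria

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "input_id": [r.criterion.input_id for r in self.results],
                "output_id": [r.criterion.output_id for r in self.results],
                "expected": [r.criterion.expected for r in self.results],
                "observed_activity": [r.observed_activity for r in self.results],
                "passed": [int(r.passed) for r in self.results],
            }
        )


def load_criteria(path: str | Path) -> list[VerificationCriterion]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in ("input_id", "output_id", "expected") if c not in df.columns]
    if missing:
        raise ValueError(f"criteria table missing column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        ev = tuple(p.strip() for p in str(row.get("evidence", "")).split(";") if p.strip())
        out.append(
            VerificationCriterion(
                input_id=row["input_id"].strip(),
                output_id=row["output_id"].strip(),
                expected=row["expected"].strip(),
                evidence=ev,
            )
        )
    return out


def run_verification(
    net: BooleanControlNetwork,
    criteria: Sequence[VerificationCriterion],
    max_steps: int = 10_000,
) -> VerificationReport:
    """Evaluate every criterion with a lone-stimulus, unperturbed run.

    Attractors are computed once per distinct input and shared across
    criteria; the aggregate score is invariant to criteria order.
    """
    if not criteria:
        raise ValueError("empty criteria list; score undefined")
    for c in criteria:
        for nid, role in ((c.input_id, "input"), (c.output_id, "output")):
            if nid not in net.index:
                raise ValueError(f"criterion references unknown {role} node {nid!r}")
        if net.node(c.input_id).klass != "input":
            raise ValueError(f"{c.input_id!r} is not input-class")
        if net.node(c.output_id).klass != "output":
            raise ValueError(f"{c.output_id!r} is not output-class")
    distinct_inputs = sorted({c.input_id for c in criteria})
    attractors = batch_attractors(
        net, [Environment([i]) for i in distinct_inputs], max_steps=max_steps
    )
    activity_by_input = dict(zip(distinct_inputs, attractors))
    results = []
    for c in criteria:
        act = float(activity_by_input[c.input_id].activity[net.index[c.output_id]])
        observed_active = act >= 0.5
        results.append(
            CriterionResult(
                criterion=c,
                observed_activity=act,
                passed=observed_active == (c.expected == "active"),
            )
        )
    return VerificationReport(results=tuple(results))
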