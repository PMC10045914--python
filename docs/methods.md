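# Methods

## Model and assumptions

polarnet implements a Boolean control network with a synchronous update
scheme: all nodes recompute simultaneously from the previous global state
via `S_{t+1} = thr(W·S_t − Θ)`, `thr(x) = 1 iff x ≥ 0`.  The model
deliberately abstracts away time scales, protein amounts and de-novo
synthesis: it targets the early response of a cell, where the decision
about polarization is made before feedback and autocrine loops act.
Consequences of these assumptions:

- Dynamics are deterministic; from a fixed start state and clamped inputs
  each run has exactly one attractor.  No asynchronous or stochastic
  update schemes are provided.
- Because `thr(0) = 1`, a node with threshold 0 and no active regulators
  is ON.  This is used twice: constitutively active nodes (default
  threshold 0, no incoming edges) and clamped-active inputs (threshold
  overridden to 0).
- All runs start all-inactive at step 0, inputs included; clamped inputs
  switch on at step 1.  The same start state is used for baseline and
  perturbed runs, so a perturbed run models treatment present from the
  beginning of stimulation rather than the re-education of an already
  settled state.  (The engine makes the other protocol easy to build —
  run, perturb, continue — but the screens use the uniform one.)

## Clamping and perturbation mechanics

Both are threshold overrides, keeping `S_{t+1} = thr(W·S_t − Θ_eff)` the
only update rule.  With `B = 1 + Σ|W|` (unreachable by any weighted input
sum): active input → 0, inactive input → +B, inhibited node → +B,
constitutively activated node → −B.  Perturbation overrides are applied
after environment overrides and win.  By default only inner nodes may be
perturbed; the screens model therapeutic inhibition of signal transducers,
not removal of stimuli or silencing of readouts.

## Attractor detection

Brent's power-of-two cycle detection runs on the deterministic step
function: a teleporting tortoise anchors at positions 2^k while the hare
steps singly, yielding the minimal period λ; two pointers λ apart then
replay from the start to find the transient length μ exactly.  Memory is
O(1) states.  `max_steps` (default 10,000) only guards misconfigured
inputs — the state space is finite, so detection always terminates; the
106-node-scale networks used here converge in tens of steps.

`batch_attractors` advances many environments as columns of one state
matrix and freezes each column at its fixed point with the exact
transient; columns still moving after a 4n+16-step window (limit cycles,
or pathologically long transients) fall back to per-column Brent.  The
test suite asserts bit-identical agreement with mapped single runs,
including on cyclic networks.

## Numerical choices

- Weights and thresholds are binary fractions (±1, ±0.5, 0); the `x ≥ 0`
  comparison is then exact in IEEE floating point, so no tolerance is
  applied anywhere in the dynamics.  Supplying weights that are not
  binary fractions technically works but forfeits this exactness.
- pI values are ratios of small integers; ΔpI differences are therefore
  exactly representable, and the synI "= 1" (additivity) bucket uses a
  tight |synI − 1| ≤ 1e-9 test rather than a loose band.
- Flip comparison uses strict inequalities (`|pI| > 0.2` on both sides);
  sign(0) is neither positive nor negative, so a pI of exactly 0 never
  flips.
- The power-law check is an ordinary least-squares line on log(count)
  vs log(degree) over occupied degree classes (counts, not frequencies;
  unbinned), reporting the regression R² and the negated slope as the
  exponent.  Degree 0 and explicitly excluded outlier degrees are left
  out; at least 3 usable classes are required.
- Betweenness is directed, unweighted, sign-blind shortest-path
  betweenness normalized by (n−1)(n−2), delegated to networkx and
  cross-checked in the tests against a path-enumeration oracle.

## Screen protocol and parameters

| parameter | default | meaning |
|---|---|---|
| τ (tau) | 0.1 | floor of the synI denominator; caps synI at &#124;ΔpI&#124;/τ when single effects vanish |
| flip threshold | 0.2 | commitment cutoff on &#124;pI&#124; for both runs of a flip |
| shift threshold | 0.4 | &#124;ΔpI&#124; beyond which a case counts as a notable shift |
| order | 1 | 1 = single targets, 2 = unordered pairs |

Environments are all 2^k − 1 non-empty input subsets in binary-counting
order over the node-table input order; the all-off environment is excluded
(an unstimulated cell is not a treatment scenario).  Eligible targets are
the inner nodes minus receptors, with TLR2 and TLR4 kept eligible.
Baseline attractors are computed once per environment and shared; order-2
synI reuses the order-1 ΔpI of the same environment.  Record order is
canonical — targets outermost, environments innermost — independent of
internal batching.  Flip direction is the sign of the perturbed pI
(the destination state).

## Verification harness

Criteria are binary expectations — a gene ON or OFF under a lone stimulus
— checked against the unperturbed attractor with only that input active.
Published evidence is usually up-/down-regulation; mapping it onto a
Boolean attractor state is the natural reading in this model class.  For
limit cycles an activity fraction ≥ 0.5 counts as active.  The aggregate
score is the fraction of criteria satisfied and is invariant to criteria
order.

## Synthetic networks: what they emulate, and what they do not

The generator builds layered nets (inputs → inner → outputs) with the
gate vocabulary of the curated model: AND gates (two +0.5 activators,
probability `and_gate_fraction` = 0.25), OR gates (one or two +1
activators, equal odds), and an optional −1 veto edge per node
(probability `inhibitory_fraction` = 0.15).  Sources are drawn with
preferential attachment (weight 1 + out-degree), giving a right-skewed,
roughly power-law inner degree distribution.  `cycle_edges` injects
back-edges among inner nodes; at 0 the net is acyclic and every attractor
is a steady state.  Outputs and inputs get alternating type-1/type-2
polarity so both pI layers are always defined.  The default layer sizes
9/75/22 mirror the curated macrophage model.  Randomness is
`numpy.random.default_rng` (PCG64); the seed is echoed in the exported
metadata and identical seeds give byte-identical exports.

What synthetic nets do **not** capture: literature-derived wiring (no
real pathway structure or crosstalk), curated per-edge evidence, the
curated model's specific proportions of technical/constitutive nodes, and
any biologically meaningful polarity assignment.  Passing tests on them
demonstrates the correctness of the algorithms — state progression,
attractor detection, index algebra, screen bookkeeping — not the biology
of any particular network.

## Problem sizes

The test suite and `scripts/acceptance.py` use: ~200 random networks with
n ≤ 12 for oracle agreement; all 511 environments of a 9/75/22 synthetic
network for the order-1 screen and the input/output pI correlation; and a
5/25/10 network with 4 injected feedback edges (31 environments, 300
target pairs, 9,300 cases) for the order-2 screen.  These sizes keep a
full run to a few seconds while exercising every code path, including the
limit-cycle fallback.

## Known limitations

- The verification and screen endpoints of the curated macrophage network
  require its supplementary node/edge/criteria tables, which are not
  bundled; see the README for how to run the protocol once those tables
  are converted to the canonical TSV schema.
- One caveat on ring fixtures: with `thr(x ≥ 0)` a threshold-0 node with a
  single +1 incoming edge is ON regardless of its source, so simple copy
  rings at Θ = 0 do not oscillate; sustained oscillation needs net
  negative feedback (an odd number of inhibitory edges in the loop, as in
  the `ring_oscillator` fixture) or intermediate thresholds (0.5).
- Screens assume 100% inhibition efficiency and stop at pairs; no partial
  efficacy, no triples.
- Large order-2 screens hold all records in memory (~100 bytes/record);
  at the million-case scale this is a few hundred MB.  Streaming export
  is the CLI's job via per-chunk writes if that ever binds.
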