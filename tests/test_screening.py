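"""Inhibition screens: enumeration, eligibility, synergy, summaries."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarnet import (
    BooleanControlNetwork,
    EdgeSpec,
    Environment,
    NodeSpec,
    Perturbation,
    ScreenConfig,
    ScreenRecord,
    SynthConfig,
    eligible_targets,
    enumerate_environments,
    find_attractor,
    generate_random_bcn,
    make_fixture,
    polarization_index,
    run_screen,
    summarize_screen,
    synergy_index,
)
from polarnet.screening import records_to_frame, summary_to_kv_frame, summary_to_text


class TestEnumerateEnvironments:
    def test_single_input_gives_one(self, synergy_net):
        assert enumerate_environments(synergy_net) == [Environment(["IN"])]

    def test_two_inputs_give_three_in_binary_order(self, and_net):
        envs = enumerate_environments(and_net)
        assert envs == [
            Environment(["IN1"]),
            Environment(["IN2"]),
            Environment(["IN1", "IN2"]),
        ]
        assert [e.bitmask(and_net) for e in envs] == [1, 2, 3]

    def test_nine_inputs_give_511(self):
        net = generate_random_bcn(SynthConfig(n_in=9, n_inner=4, n_out=2, seed=0))
        assert len(enumerate_environments(net)) == 511

    def test_no_inputs_is_an_error(self):
        net = BooleanControlNetwork([NodeSpec(id="X", klass="inner", is_constitutive=True)], [])
        with pytest.raises(ValueError, match="no input nodes"):
            enumerate_environments(net)


class TestEligibleTargets:
    def _net(self, inner_specs):
        nodes = [NodeSpec(id="IN", klass="input")]
        edges = []
        for nid, receptor in inner_specs:
            nodes.append(NodeSpec(id=nid, klass="inner", is_receptor=receptor))
            edges.append(EdgeSpec("IN", nid, 1.0))
        return BooleanControlNetwork(nodes, edges)

    def test_plain_inner_nodes_all_eligible(self):
        net = self._net([("A", False), ("B", False), ("C", False)])
        assert eligible_targets(net) == ["A", "B", "C"]

    def test_receptor_excluded(self):
        net = self._net([("IL4R", True)])
        assert eligible_targets(net) == []

    def test_tlr2_and_tlr4_receptors_stay(self):
        net = self._net([("TLR2", True), ("TLR4", True), ("IL4R", True), ("STAT6", False)])
        assert eligible_targets(net) == ["TLR2", "TLR4", "STAT6"]

    def test_inputs_and_outputs_never_eligible(self, and_net):
        assert eligible_targets(and_net) == ["GATE"]


class TestSynergyIndex:
    def test_small_singles_floored_by_tau(self):
        # pair effect 0.57 against singles 0.05 + 0.0 -> 0.57 / 0.1
        assert synergy_index(0.57, 0.05, 0.0, 0.1) == pytest.approx(5.7)

    def test_plain_ratio(self):
        assert synergy_index(0.4, 0.3, 0.2, 0.1) == pytest.approx(0.8)

    def test_all_zero(self):
        assert synergy_index(0.0, 0.0, 0.0, 0.1) == 0.0

    def test_tau_must_be_positive(self):
        with pytest.raises(ValueError):
            synergy_index(0.1, 0.1, 0.1, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2), st.floats(0.01, 1)
    )
    def test_nonnegative_and_capped_by_delta_over_tau(self, dab, da, db, tau):
        v = synergy_index(dab, da, db, tau)
        assert v >= 0.0
        assert v <= abs(dab) / tau + 1e-12


class TestRunScreen:
    def test_order1_record_count_identity(self):
        net = generate_random_bcn(SynthConfig(n_in=3, n_inner=8, n_out=4, seed=2))
        records = run_screen(net, ScreenConfig(order=1))
        assert len(records) == len(eligible_targets(net)) * 7

    def test_order2_record_count_identity(self):
        net = generate_random_bcn(SynthConfig(n_in=2, n_inner=6, n_out=4, seed=3))
        records = run_screen(net, ScreenConfig(order=2))
        t = len(eligible_targets(net))
        assert len(records) == t * (t - 1) // 2 * 3

    def test_three_targets_one_input_order2_gives_three(self):
        nodes = [NodeSpec(id="IN", klass="input")]
        edges = []
        for nid in ("A", "B", "C"):
            nodes.append(NodeSpec(id=nid, klass="inner"))
            edges.append(EdgeSpec("IN", nid, 1.0))
        nodes += [
            NodeSpec(id="O1", klass="output", polarity="type1"),
            NodeSpec(id="O2", klass="output", polarity="type2"),
        ]
        edges += [EdgeSpec("A", "O1", 1.0), EdgeSpec("A", "O2", -1.0)]
        net = BooleanControlNetwork(nodes, edges)
        assert len(run_screen(net, ScreenConfig(order=2))) == 3

    def test_pair_symmetry(self):
        net = generate_random_bcn(SynthConfig(n_in=2, n_inner=5, n_out=4, seed=4))
        a, b = eligible_targets(net)[:2]
        fwd = run_screen(net, ScreenConfig(order=2), targets=[a, b])
        rev = run_screen(net, ScreenConfig(order=2), targets=[b, a])
        for r1, r2 in zip(fwd, rev):
            assert set(r1.targets) == set(r2.targets)
            assert r1.pI_pert == r2.pI_pert and r1.synI == r2.synI

    def test_null_perturbation_of_inactive_node(self, and_net):
        """Inhibiting a node that is off in the baseline leaves pI unchanged."""
        records = run_screen(and_net, ScreenConfig(order=1))
        by_env = {r.env: r for r in records}
        # with a single input the AND gate never fires, so inhibiting it is null
        assert by_env[Environment(["IN1"])].delta_pI == 0.0
        assert by_env[Environment(["IN2"])].delta_pI == 0.0
        # with both inputs the gate carries the signal
        assert by_env[Environment(["IN1", "IN2"])].delta_pI == -1.0

    def test_agrees_with_naive_per_case_reimplementation(self):
        """Batched screen == unbatched loop over find_attractor per case."""
        net = generate_random_bcn(
            SynthConfig(n_in=3, n_inner=5, n_out=2, cycle_edges=2, seed=9)
        )
        cfg = ScreenConfig(order=2)
        records = run_screen(net, cfg)
        envs = enumerate_environments(net)
        targets = eligible_targets(net)
        naive = {}
        base = {e: polarization_index(find_attractor(net, e), net).pI for e in envs}
        single = {
            (t, e): polarization_index(
                find_attractor(net, e, Perturbation(inhibited=[t])), net
            ).pI
            for t in targets
            for e in envs
        }
        for a, b in combinations(targets, 2):
            for e in envs:
                att = find_attractor(net, e, Perturbation(inhibited=[a, b]))
                pi = polarization_index(att, net).pI
                d_ab = pi - base[e]
                naive[(a, b, e)] = (
                    pi,
                    d_ab,
                    att.period,
                    synergy_index(d_ab, single[(a, e)] - base[e], single[(b, e)] - base[e], cfg.tau),
                )
        assert len(records) == len(naive)
        for r in records:
            pi, d, period, syn = naive[(r.targets[0], r.targets[1], r.env)]
            assert r.pI_pert == pi and r.delta_pI == d
            assert r.period == period and r.synI == pytest.approx(syn)


class TestSummarize:
    def _rec(self, delta, base=0.0, flip=0, period=1, syn=None):
        return ScreenRecord(
            env=Environment(["IN"]),
            targets=("A", "B") if syn is not None else ("A",),
            pI_base=base,
            pI_pert=base + delta,
            delta_pI=delta,
            flip=flip,
            period=period,
            synI=syn,
        )

    def test_hand_tallied_buckets(self):
        records = [
            self._rec(0.5),
            self._rec(0.41),
            self._rec(-0.6),
            self._rec(0.1),
            self._rec(-0.3, period=2),
        ]
        s = summarize_screen(records, ScreenConfig(order=1))
        assert s["n_cases"] == 5
        assert s["shift_up_count"] == 2 and s["shift_up_pct"] == 40.0
        assert s["shift_down_count"] == 1 and s["shift_down_pct"] == 20.0
        assert s["limit_cycle_count"] == 1

    def test_flip_directions_split_by_destination(self):
        records = [
            self._rec(0.6, base=-0.3, flip=1),   # toward inflammation
            self._rec(-0.6, base=0.3, flip=1),   # toward tissue protection
            self._rec(-0.6, base=0.3, flip=1),
        ]
        s = summarize_screen(records, ScreenConfig(order=1))
        assert s["flips_toward_inflammation"] == 1
        assert s["flips_toward_tissue_protection"] == 2

    def test_synI_buckets_partition(self):
        records = [
            self._rec(0.1, syn=0.5),
            self._rec(0.1, syn=1.0),
            self._rec(0.1, syn=1.0 + 1e-12),  # inside the additivity tolerance
            self._rec(0.1, syn=1.5),
        ]
        s = summarize_screen(records, ScreenConfig(order=2))
        counts = (s["synI_below_1_count"], s["synI_equal_1_count"], s["synI_above_1_count"])
        assert counts == (1, 2, 1)
        assert sum(counts) == s["n_cases"]
        assert (
            s["synI_below_1_pct"] + s["synI_equal_1_pct"] + s["synI_above_1_pct"]
        ) == pytest.approx(100.0)

    def test_flip_involvement_fractions(self):
        records = [
            self._rec(0.8, base=-0.3, flip=1, syn=2.0),
            self._rec(0.8, base=-0.3, flip=1, syn=2.0),
        ]
        records.append(
            ScreenRecord(
                env=Environment(["IN"]), targets=("A", "C"), pI_base=-0.3,
                pI_pert=0.5, delta_pI=0.8, flip=1, period=1, synI=2.0,
            )
        )
        s = summarize_screen(records, ScreenConfig(order=2))
        inv = s["flip_involvement_inflammatory"]
        assert inv["A"] == 100.0 and inv["B"] == pytest.approx(66.67) and inv["C"] == pytest.approx(33.33)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_screen([], ScreenConfig())

    def test_text_and_kv_renderings(self):
        records = [self._rec(0.5, syn=1.0)]
        s = summarize_screen(records, ScreenConfig(order=2))
        text = summary_to_text(s)
        assert "cases: 1" in text and "synI buckets" in text
        kv = summary_to_kv_frame(s)
        assert {"n_cases", "synI_equal_1_count"} <= set(kv["key"])


def test_records_frame_schema(synergy_net):
    records = run_screen(synergy_net, ScreenConfig(order=2))
    df = records_to_frame(records, synergy_net)
    assert list(df.columns) == [
        "env_bitmask", "env_ids", "target1", "target2", "pI_base", "pI_pert",
        "delta_pI", "period", "flip", "flip_direction", "synI",
    ]
    assert df.loc[0, "target2"] == "P2"


def test_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(tau=0.0)
    with pytest.raises(ValueError):
        ScreenConfig(order=3)
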