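"""Architecture calls, Fitch parsimony, and the presence/absence report."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from spo0scan import (
    call_architecture,
    fitch_transition_count,
    presence_absence_report,
)
from spo0scan.model import KinaseRecord, Role, Spo0Candidate, Spo0Inventory


def _cand(role: str) -> Spo0Candidate:
    ev = {"rec_coverage": 0.95} if role == "SPO0F" else {"identity": 0.4} if role == "SPO0B" else {}
    return Spo0Candidate(role=role, gene_id=f"g_{role}", genome_id="g", evidence=ev)


def _inventory(a=False, f=False, b=False, gid="g") -> Spo0Inventory:
    return Spo0Inventory(
        genome_id=gid,
        spo0a=[_cand("SPO0A")] if a else [],
        spo0f=_cand("SPO0F") if f else None,
        spo0b=_cand("SPO0B") if b else None,
    )


class TestCallArchitecture:
    @pytest.mark.parametrize(
        "a,f,b,expected",
        [
            (True, True, True, "PHOSPHORELAY"),
            (True, False, False, "DIRECT"),
            (True, False, True, "PARTIAL_RELAY"),
            (True, True, False, "PARTIAL_RELAY"),
            (False, False, False, "NO_SPO0"),
        ],
    )
    def test_rule(self, a, f, b, expected):
        assert call_architecture(_inventory(a, f, b)).label == expected

    def test_pure_function(self):
        inv = _inventory(True, True, True)
        assert call_architecture(inv).label == call_architecture(inv).label


# -- independent brute-force small-parsimony oracle ----------------------

def brute_force_min_changes(tree, labels) -> int:
    """Exhaustive minimum over all internal labelings of a nested-tuple tree."""
    internals = []

    def walk(node):
        if isinstance(node, str):
            return
        internals.append(id(node))
        for child in node:
            walk(child)

    walk(tree)
    states = sorted(set(labels.values()))
    best = float("inf")

    def cost(node, assignment):
        if isinstance(node, str):
            return 0, labels[node]
        total = 0
        mine = assignment[id(node)]
        for child in node:
            c, child_state = cost(child, assignment)
            total += c + (child_state != mine)
        return total, mine

    for combo in itertools.product(states, repeat=len(internals)):
        assignment = dict(zip(internals, combo))
        total, _ = cost(tree, assignment)
        best = min(best, total)
    return int(best)


def to_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(to_newick(c) for c in tree) + ")"


def random_binary_tree(rng, leaves):
    nodes = [str(l) for l in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


class TestFitch:
    def test_uniform_labels_need_no_change(self):
        labels = {x: "PHOSPHORELAY" for x in "ABCD"}
        assert fitch_transition_count("((A,B),(C,D));", labels) == 0

    def test_alternating_four_leaf_tree_needs_two(self):
        labels = {"A": "relay", "B": "direct", "C": "relay", "D": "direct"}
        assert fitch_transition_count("((A,B),(C,D));", labels) == 2

    def test_cherry_needs_one(self):
        assert fitch_transition_count("(A,B);", {"A": "relay", "B": "direct"}) == 1

    def test_pruning_removes_out_of_scope_states(self):
        labels = {"A": "relay", "B": "NO_SPO0", "C": "relay", "D": "relay"}
        assert fitch_transition_count("((A,B),(C,D));", labels, states=["relay", "direct"]) == 0

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(ValueError, match="label"):
            fitch_transition_count("((A,B),(C,D));", {"A": "x", "B": "x", "C": "x"})

    def test_count_bounded_by_leaves_minus_one(self):
        labels = {x: s for x, s in zip("ABCDE", ["a", "b", "c", "a", "b"])}
        count = fitch_transition_count("((A,(B,C)),(D,E));", labels)
        assert 0 < count <= 4

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            leaves = [f"L{k}" for k in range(n)]
            tree = random_binary_tree(rng, leaves)
            states = ["relay", "direct", "partial"][: int(rng.integers(2, 4))]
            labels = {l: states[int(rng.integers(0, len(states)))] for l in leaves}
            expected = brute_force_min_changes(tree, labels)
            got = fitch_transition_count(to_newick(tree) + ";", labels)
            assert got == expected, (to_newick(tree), labels)

    def test_polytomy_resolved_deterministically(self):
        labels = {"A": "x", "B": "y", "C": "x", "D": "y"}
        first = fitch_transition_count("(A,B,C,D);", labels)
        second = fitch_transition_count("(A,B,C,D);", labels)
        assert first == second


class TestReport:
    def test_two_genome_booleans(self):
        invs = [_inventory(True, True, True, gid="g1"), _inventory(True, False, False, gid="g2")]
        df = presence_absence_report(invs)
        assert list(df.genome_id) == ["g1", "g2"]
        assert list(df.architecture) == ["PHOSPHORELAY", "DIRECT"]
        assert bool(df.loc[0, "spo0f"]) and not bool(df.loc[1, "spo0f"])

    def test_tree_order_and_flagging_of_extra_genomes(self):
        invs = [_inventory(True, True, True, gid="g1"), _inventory(True, False, False, gid="gX")]
        df = presence_absence_report(invs, tree="(g1,g2);")
        assert list(df.genome_id) == ["g1", "g2", "gX"]
        assert df.loc[1, "architecture"] == "missing"  # leaf without inventory
        assert not bool(df.loc[2, "in_tree"])  # genome absent from tree, appended

    def test_empty_input_gives_header_only(self):
        df = presence_absence_report([])
        assert df.empty and list(df.columns)[0] == "genome_id"

    def test_orphan_kinase_columns(self):
        inv = _inventory(True, True, True, gid="g1")
        inv.kinases = [
            KinaseRecord("k1", "g1", is_orphan=True, has_nterm_pas=True),
            KinaseRecord("k2", "g1", is_orphan=False),
        ]
        df = presence_absence_report([inv])
        assert bool(df.loc[0, "orphan_kinase"]) and bool(df.loc[0, "pas_orphan"])
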