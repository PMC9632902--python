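"""Indel encodings, history inference and event extraction."""

import itertools

import numpy as np
import pytest

from pogasr.core_model import Alignment, PhyloTree
from pogasr.indel import (
    INDEL_OPTIONS,
    NO_EDGE,
    IndelEvent,
    UnsupportedOptionError,
    be_parsimony,
    encode_indels,
    extract_indel_events,
    infer_discrete_history,
    infer_indels,
)
from pogasr.pog import build_extant_pog, build_input_pog

from conftest import (
    brute_force_parsimony,
    random_bifurcating_tree,
    random_gapped_alignment,
)


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------

class TestEncodings:
    def test_ps_states(self):
        aln = Alignment(["a", "b"], ["ACDE", "AC-E"])
        enc = encode_indels(aln, "PS")
        assert enc.content.shape == (2, 4)
        assert not enc.content[1, 2]
        assert enc.content[:, [0, 1, 3]].all()

    def test_sic_events_and_states(self):
        aln = Alignment(["r1", "r2", "r3"], ["A--D", "A-CD", "ACCD"])
        enc = encode_indels(aln, "SIC")
        # gap runs: columns 2-3 (r1) and column 2 (r2)
        assert enc.events == [(2, 2), (2, 3)]
        assert enc.states[(2, 2)] == ["inapplicable", "present", "absent"]
        assert enc.states[(2, 3)] == ["present", "absent", "absent"]
        # flanking-edge coordinates of the two events
        assert [(s - 1, e + 1) for s, e in enc.events] == [(1, 3), (1, 4)]

    def test_sic_equal_run_is_present_not_inapplicable(self):
        aln = Alignment(["a", "b"], ["A--D", "A--D"])
        enc = encode_indels(aln, "SIC")
        assert enc.states[(2, 3)] == ["present", "present"]

    def test_be_candidates(self):
        aln = Alignment(["a", "b"], ["ACDE", "AC-E"])
        enc = encode_indels(aln, "BE")
        assert enc.forward[2] == [3, 4]
        assert enc.backward[4] == [2, 3]

    def test_be_no_edge_augmentation(self):
        aln = Alignment(["a", "b"], ["ACDE", "AC-E"])
        enc = encode_indels(aln, "BE", with_no_edge=True)
        assert NO_EDGE in enc.forward[3]       # some extant lacks column 3
        assert NO_EDGE not in enc.forward[2]   # all extants have column 2

    def test_unknown_method_rejected(self):
        aln = Alignment(["a"], ["ACDE"])
        with pytest.raises(UnsupportedOptionError):
            encode_indels(aln, "XYZ")


# ---------------------------------------------------------------------------
# Discrete history engine
# ---------------------------------------------------------------------------

class TestDiscreteHistory:
    def test_single_change_at_leaf(self):
        tree = PhyloTree.from_newick("((l1:1,l2:1):1,(l3:1,l4:1):1);")
        leaf = {"l1": "p", "l2": "p", "l3": "p", "l4": "a"}
        chosen, cost = infer_discrete_history(tree, leaf, "parsimony",
                                              state_set=["p", "a"])
        assert cost == 1
        assert chosen["N0"] == frozenset({"p"})

    def test_all_identical_costs_zero(self):
        tree = PhyloTree.from_newick("((l1:1,l2:1):1,l3:1);")
        chosen, cost = infer_discrete_history(
            tree, {"l1": "x", "l2": "x", "l3": "x"}, "parsimony",
            state_set=["x", "y"])
        assert cost == 0
        assert all(v == frozenset({"x"}) for v in chosen.values())

    def test_symmetric_split_ties_at_root(self):
        tree = PhyloTree.from_newick("((l1:1,l2:1):1,(l3:1,l4:1):1);")
        leaf = {"l1": "p", "l2": "a", "l3": "p", "l4": "a"}
        chosen, cost = infer_discrete_history(tree, leaf, "parsimony",
                                              state_set=["p", "a"])
        assert cost == 2
        assert chosen["N0"] == frozenset({"p", "a"})

    def test_invalid_leaf_state_rejected(self):
        tree = PhyloTree.from_newick("(l1:1,l2:1);")
        with pytest.raises(Exception):
            infer_discrete_history(tree, {"l1": "z", "l2": "p"}, "parsimony",
                                   state_set=["p", "a"])

    @pytest.mark.parametrize("seed", range(20))
    def test_parsimony_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(3, 6))
        tree = random_bifurcating_tree(rng, n_leaves)
        states = ["s0", "s1", "s2"][: int(rng.integers(2, 4))]
        leaf_states = {}
        for leaf in tree.leaf_labels:
            if rng.random() < 0.2:
                leaf_states[leaf] = None
            else:
                leaf_states[leaf] = states[int(rng.integers(len(states)))]
        chosen, cost = infer_discrete_history(tree, leaf_states, "parsimony",
                                              state_set=states)
        o_cost, o_sets = brute_force_parsimony(tree, leaf_states, states)
        assert cost == o_cost
        assert chosen == o_sets

    @pytest.mark.parametrize("seed", range(10))
    def test_ml_matches_enumeration(self, seed):
        # exhaustive max-product over the uniform model
        import math
        from pogasr.indel import _uniform_logP

        rng = np.random.default_rng(100 + seed)
        tree = random_bifurcating_tree(rng, int(rng.integers(3, 5)),
                                       bl_range=(0.05, 1.5))
        states = ["u", "v", "w"]
        leaf_states = {leaf: states[int(rng.integers(3))]
                       for leaf in tree.leaf_labels}
        chosen, _ = infer_discrete_history(tree, leaf_states, "ML",
                                           state_set=states)
        ancestors = tree.ancestor_labels
        best, best_assign = -np.inf, None
        for combo in itertools.product(states, repeat=len(ancestors)):
            assign = dict(zip(ancestors, combo))
            lp = 0.0
            for node in tree.preorder():
                if node.parent is None:
                    continue
                ls, ld = _uniform_logP(3, node.length)
                child = (leaf_states[node.label] if node.is_leaf
                         else assign[node.label])
                lp += ls if child == assign[node.parent.label] else ld
            if lp > best + 1e-12:
                best, best_assign = lp, assign
        for k in ancestors:
            assert best_assign[k] in chosen[k], (k, chosen[k], best_assign)


# ---------------------------------------------------------------------------
# Bi-directional edge parsimony
# ---------------------------------------------------------------------------

def _be_oracle_supports(alignment, tree, with_no_edge=False):
    """Expected per-ancestor support matrices by exhaustive enumeration of
    per-ancestor neighbour assignments, independently per position and
    direction (missing extants are free; positions absent from an
    ancestor's whole extant subtree are excluded under the legacy rule)."""
    n = alignment.n_cols
    end = n + 1
    ip = build_input_pog(alignment)
    pogs = {sid: build_extant_pog(alignment, sid) for sid in alignment.ids}
    chains = {sid: [0] + p.positions + [end] for sid, p in pogs.items()}
    nxt = {sid: dict(zip(c[:-1], c[1:])) for sid, c in chains.items()}
    prv = {sid: dict(zip(c[1:], c[:-1])) for sid, c in chains.items()}
    subtree = {k: set(tree.subtree_leaves(k)) for k in tree.ancestor_labels}
    support = {k: np.zeros((n + 2, n + 2), dtype=int)
               for k in tree.ancestor_labels}
    for direction in ("forward", "backward"):
        look = nxt if direction == "forward" else prv
        refs = ([i for i in range(0, end) if ip.next_nodes(i)]
                if direction == "forward"
                else [i for i in range(1, end + 1) if ip.prev_nodes(i)])
        for i in refs:
            cands = (ip.next_nodes(i) if direction == "forward"
                     else ip.prev_nodes(i))
            terminal = i == 0 or i == end
            if with_no_edge and not terminal and \
                    any(i not in look[s] for s in alignment.ids):
                cands = cands + [NO_EDGE]
            leaf_states = {}
            for sid in alignment.ids:
                if i in look[sid]:
                    leaf_states[sid] = look[sid][i]
                else:
                    leaf_states[sid] = (NO_EDGE if with_no_edge and not terminal
                                        else None)
            _, sets = brute_force_parsimony(tree, leaf_states, cands)
            for k, picks in sets.items():
                for b in picks:
                    if b != NO_EDGE:
                        support[k][i, b] = 1
    if with_no_edge:
        return support
    # legacy rule: contract columns absent from the ancestor's whole
    # extant subtree (independent DFS-based bridging)
    for k in tree.ancestor_labels:
        content = set()
        for s in subtree[k]:
            content.update(pogs[s].positions)
        excluded = set(range(1, n + 1)) - content
        support[k] = _dfs_contract(support[k], excluded)
    return support


def _dfs_contract(S, excluded):
    """Bridge edges over excluded nodes, separately for the forward
    (above-diagonal) and backward (below-diagonal) edge sets."""
    m = S.shape[0]
    out = np.zeros_like(S)
    for orientation in ("fwd", "bwd"):
        def succ(x):
            if orientation == "fwd":
                return [b for b in range(x + 1, m) if S[x, b]]
            return [a for a in range(0, x) if S[x, a]]
        for a in range(m):
            if a in excluded:
                continue
            stack = list(succ(a))
            seen = set()
            while stack:
                b = stack.pop()
                if b in seen:
                    continue
                seen.add(b)
                if b in excluded:
                    stack.extend(succ(b))
                else:
                    out[a, b] = 1
    return out


class TestBEParsimony:
    def test_spec_worked_example(self):
        aln = Alignment(["s1", "s2", "s3", "s4"],
                        ["ACDE", "ACDE", "ACDE", "AC-E"])
        tree = PhyloTree.from_newick("((s1:1,s2:1):1,(s3:1,s4:1):1);")
        pogs = {sid: build_extant_pog(aln, sid) for sid in aln.ids}
        support = be_parsimony(tree, pogs, build_input_pog(aln))
        root = support["N0"]
        # root keeps the D column: (2,3) and (3,4) bi-directional
        assert root[2, 3] == 1 and root[3, 2] == 1
        assert root[3, 4] == 1 and root[4, 3] == 1
        # the skip edge (2,4) is not optimal at the root in either direction
        assert root[2, 4] == 0 and root[4, 2] == 0

    def test_identical_chains_zero_cost(self):
        aln = Alignment(["a", "b", "c"], ["A-DE"] * 3)
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        pogs = {sid: build_extant_pog(aln, sid) for sid in aln.ids}
        support = be_parsimony(tree, pogs, build_input_pog(aln))
        expected = build_extant_pog(aln, "a").edge_set()
        for k, S in support.items():
            got = {(a, b) for a, b in zip(*np.nonzero(np.triu(S, 1)))}
            back = {(b, a) for a, b in zip(*np.nonzero(np.tril(S, -1)))}
            assert got == expected
            assert back == expected     # fully bi-directional

    @pytest.mark.parametrize("with_no_edge", [False, True])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed, with_no_edge):
        rng = np.random.default_rng(1000 + seed)
        n_leaves = int(rng.integers(3, 5))
        n_cols = int(rng.integers(3, 7))
        aln = random_gapped_alignment(rng, n_leaves, n_cols)
        tree = random_bifurcating_tree(rng, n_leaves)
        # rename alignment ids to the tree leaves
        aln = Alignment(tree.leaf_labels, aln.rows)
        pogs = {sid: build_extant_pog(aln, sid) for sid in aln.ids}
        support = be_parsimony(tree, pogs, build_input_pog(aln),
                               with_no_edge=with_no_edge)
        expected = _be_oracle_supports(aln, tree, with_no_edge)
        for k in tree.ancestor_labels:
            assert np.array_equal(support[k], expected[k]), k


# ---------------------------------------------------------------------------
# Six-option dispatch
# ---------------------------------------------------------------------------

class TestInferIndels:
    @pytest.mark.parametrize("option", INDEL_OPTIONS)
    def test_ungapped_alignment_full_chain(self, option):
        aln = Alignment(["a", "b", "c", "d"], ["ACDE"] * 4)
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        pogs = infer_indels(aln, tree, option)
        for k, pog in pogs.items():
            assert pog.positions() == [1, 2, 3, 4], (option, k)

    def test_sic_and_be_agree_on_toy(self, toy_alignment, toy_tree):
        sic = infer_indels(toy_alignment, toy_tree, "SIC-P")
        be = infer_indels(toy_alignment, toy_tree, "BE-P")
        assert sic["N0"].positions() == be["N0"].positions() == [1, 2, 3, 4]

    @pytest.mark.parametrize("option", INDEL_OPTIONS)
    def test_no_dangling_nodes(self, option):
        rng = np.random.default_rng(5)
        aln = random_gapped_alignment(rng, 5, 8)
        tree = random_bifurcating_tree(rng, 5)
        aln = Alignment(tree.leaf_labels, aln.rows)
        from pogasr.pog import reachable_positions
        for k, pog in infer_indels(aln, tree, option).items():
            touched = set(np.nonzero(pog.support.sum(axis=0)
                                     + pog.support.sum(axis=1))[0])
            touched -= {0, aln.n_cols + 1}
            assert touched == set(pog.positions()), (option, k)

    def test_unknown_option_rejected(self, toy_alignment, toy_tree):
        with pytest.raises(UnsupportedOptionError):
            infer_indels(toy_alignment, toy_tree, "FOO-P")

    def test_extants_never_altered(self, toy_alignment, toy_tree):
        before = {sid: build_extant_pog(toy_alignment, sid).edges
                  for sid in toy_alignment.ids}
        infer_indels(toy_alignment, toy_tree, "BE-P")
        after = {sid: build_extant_pog(toy_alignment, sid).edges
                 for sid in toy_alignment.ids}
        assert before == after


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

class TestExtractIndelEvents:
    def test_simple_deletion(self):
        evs = extract_indel_events([1, 2, 3, 4], [1, 2, 4], "b1")
        assert [(e.kind, e.start, e.end) for e in evs] == [("deletion", 3, 3)]
        assert evs[0].edge == (2, 4)

    def test_identical_sets_empty(self):
        assert extract_indel_events([1, 2, 3], [1, 2, 3], "b") == []

    def test_simple_insertion(self):
        evs = extract_indel_events([1, 4], [1, 2, 3, 4], "b1")
        assert [(e.kind, e.start, e.end) for e in evs] == [("insertion", 2, 3)]

    def test_mixed_events(self):
        evs = extract_indel_events([1, 2, 5, 6], [1, 3, 4, 6], "b")
        keys = {(e.kind, e.start, e.end) for e in evs}
        assert keys == {("deletion", 2, 2), ("deletion", 5, 5),
                        ("insertion", 3, 4)}

    def test_runs_respect_parent_contiguity(self):
        # column 3 absent from both: it does not split the deletion run 2..4
        evs = extract_indel_events([1, 2, 4, 5], [1, 5], "b")
        assert [(e.kind, e.start, e.end) for e in evs] == [("deletion", 2, 4)]
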