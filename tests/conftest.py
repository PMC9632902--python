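"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's inference code paths: joint
and marginal reconstruction are checked against full enumeration over
all ancestor-state combinations, edge parsimony against enumeration of
all per-ancestor assignments, and path extraction against exhaustive
path enumeration.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from pogasr.core_model import Alignment, PhyloTree, SubstitutionModel, TreeNode


# ---------------------------------------------------------------------------
# Instance generators
# ---------------------------------------------------------------------------

def random_bifurcating_tree(rng: np.random.Generator, n_leaves: int,
                            bl_range: Tuple[float, float] = (0.01, 2.0)
                            ) -> PhyloTree:
    """Random topology by sequential joining, uniform branch lengths."""
    nodes = [TreeNode(f"l{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode()
        a.length = float(rng.uniform(*bl_range))
        b.length = float(rng.uniform(*bl_range))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return PhyloTree(nodes[0])


def random_reversible_model(rng: np.random.Generator, k: int = 4,
                            alphabet: Sequence[str] = "ACDE"
                            ) -> SubstitutionModel:
    """A random time-reversible model over a small alphabet."""
    ex = rng.uniform(0.2, 2.0, size=(k, k))
    ex = (ex + ex.T) / 2
    pi = rng.dirichlet(np.full(k, 5.0))
    Q = ex * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SubstitutionModel("random", Q, pi, alphabet=tuple(alphabet[:k]))


def random_gapped_alignment(rng: np.random.Generator, n_seqs: int,
                            n_cols: int, gap_prob: float = 0.3) -> Alignment:
    """Random alignment with gap runs; every column has >= 1 residue."""
    letters = "ACDEFGHIKL"
    while True:
        rows = []
        for _ in range(n_seqs):
            row = [rng.choice(list(letters)) if rng.random() > gap_prob else "-"
                   for _ in range(n_cols)]
            rows.append("".join(row))
        cols_ok = all(any(r[i] != "-" for r in rows) for i in range(n_cols))
        if cols_ok and any(r.replace("-", "") for r in rows):
            return Alignment([f"l{i + 1}" for i in range(n_seqs)], rows)


# ---------------------------------------------------------------------------
# Brute-force likelihood oracles
# ---------------------------------------------------------------------------

def _tree_factors(tree: PhyloTree, model: SubstitutionModel, rate: float = 1.0):
    """Per-branch transition matrices for enumeration."""
    return {
        node.label: model.transition_probabilities(node.length, rate)
        for node in tree.preorder() if node.parent is not None
    }


def brute_force_joint(tree: PhyloTree, leaf_chars: Dict[str, str],
                      model: SubstitutionModel, rate: float = 1.0
                      ) -> Tuple[Dict[str, str], float]:
    """argmax over all ancestor-state combinations of the joint probability
    (stationary prior at the root); ties broken by lexicographic state
    combination in preorder ancestor order."""
    P = _tree_factors(tree, model, rate)
    ancestors = tree.ancestor_labels
    na = len(model.alphabet)
    best_lp, best_assign = -np.inf, None
    for combo in itertools.product(range(na), repeat=len(ancestors)):
        assign = dict(zip(ancestors, combo))
        lp = np.log(model.pi[assign[tree.root.label]])
        ok = True
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps = assign[node.parent.label]
            if node.is_leaf:
                lik = model.char_likelihood(leaf_chars[node.label])
                v = float(P[node.label][ps] @ lik)
            else:
                v = float(P[node.label][ps, assign[node.label]])
            if v <= 0:
                ok = False
                break
            lp += np.log(v)
        if ok and lp > best_lp + 1e-12:
            best_lp, best_assign = lp, assign
    states = {k: model.alphabet[v] for k, v in best_assign.items()}
    return states, float(best_lp)


def brute_force_marginal(tree: PhyloTree, leaf_chars: Dict[str, str],
                         model: SubstitutionModel, query: str,
                         rate: float = 1.0) -> np.ndarray:
    """Exact posterior at one ancestor by summing over all other ancestors."""
    P = _tree_factors(tree, model, rate)
    ancestors = tree.ancestor_labels
    na = len(model.alphabet)
    post = np.zeros(na)
    for combo in itertools.product(range(na), repeat=len(ancestors)):
        assign = dict(zip(ancestors, combo))
        p = model.pi[assign[tree.root.label]]
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps = assign[node.parent.label]
            if node.is_leaf:
                lik = model.char_likelihood(leaf_chars[node.label])
                p *= float(P[node.label][ps] @ lik)
            else:
                p *= float(P[node.label][ps, assign[node.label]])
        post[assign[query]] += p
    return post / post.sum()


# ---------------------------------------------------------------------------
# Brute-force parsimony oracle
# ---------------------------------------------------------------------------

def brute_force_parsimony(tree: PhyloTree,
                          leaf_states: Dict[str, Optional[object]],
                          states: Sequence[object]
                          ) -> Tuple[float, Dict[str, frozenset]]:
    """Minimum total unit-cost changes over all per-ancestor assignments;
    missing leaves (None) cost nothing for any parent state.  Returns the
    minimum cost and, per ancestor, the set of states occurring in at
    least one optimal assignment."""
    ancestors = tree.ancestor_labels
    best = np.inf
    sets: Dict[str, set] = {k: set() for k in ancestors}
    for combo in itertools.product(states, repeat=len(ancestors)):
        assign = dict(zip(ancestors, combo))
        cost = 0
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps = assign[node.parent.label]
            if node.is_leaf:
                obs = leaf_states[node.label]
                if obs is not None and obs != ps:
                    cost += 1
            elif assign[node.label] != ps:
                cost += 1
        if cost < best:
            best = cost
            sets = {k: {assign[k]} for k in ancestors}
        elif cost == best:
            for k in ancestors:
                sets[k].add(assign[k])
    return float(best), {k: frozenset(v) for k, v in sets.items()}


# ---------------------------------------------------------------------------
# Path enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_paths(out_edges: Dict[int, List[int]], start: int,
                    end: int) -> List[Tuple[int, ...]]:
    """All complete start -> end paths in a DAG."""
    paths: List[Tuple[int, ...]] = []

    def walk(node: int, acc: Tuple[int, ...]) -> None:
        if node == end:
            paths.append(acc)
            return
        for nxt in out_edges.get(node, ()):
            walk(nxt, acc + (nxt,))

    walk(start, (start,))
    return paths


# ---------------------------------------------------------------------------
# Common fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(["s1", "s2", "s3", "s4"],
                     ["ACDE", "ACDE", "ACDE", "AC-E"])


@pytest.fixture
def toy_tree() -> PhyloTree:
    return PhyloTree.from_newick("((s1:0.2,s2:0.3):0.2,(s3:0.3,s4:0.2):0.3);")
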