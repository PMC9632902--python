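"""Exact joint and marginal ML inference of ancestral character states.

Each alignment column is modelled independently on a *position-specific
tree*: the input tree restricted to the nodes inferred (by indel
inference) to have content at that column, with branch lengths summed
additively through elided nodes.  When the restriction disconnects the
tree, each connected component is inferred independently from its own
top node with the model's stationary distribution as prior.

Joint inference is an exact max-product dynamic programme with
traceback (ties broken lexicographically by alphabet order); marginal
inference is exact sum-product (inside-outside) with per-node rescaling
to avoid underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core_model import (
    Alignment,
    InvalidParameterError,
    PhyloTree,
    PogasrError,
    RateVector,
    SubstitutionModel,
)
from .pog import AncestorPOG
from .indel import infer_indels


class EmptyPositionTreeError(PogasrError):
    pass


class NodeMissingAtPositionError(PogasrError, KeyError):
    pass


@dataclass
class PNode:
    """A node of a position-specific tree component."""

    label: str
    is_leaf: bool
    length: float                      # distance to parent within the component
    children: List["PNode"] = field(default_factory=list)


@dataclass
class PositionTree:
    """The input tree restricted to nodes with content at one column.

    ``components`` are the maximal connected content regions, each with a
    unique top node, inferred independently.
    """

    column: int
    components: List[PNode]
    rate: float = 1.0

    def ancestors(self) -> List[str]:
        out: List[str] = []
        for top in self.components:
            stack = [top]
            while stack:
                node = stack.pop()
                if not node.is_leaf:
                    out.append(node.label)
                stack.extend(node.children)
        return out


def build_position_tree(
    tree: PhyloTree,
    position_sets: Dict[str, Set[int]],
    column: int,
    rate: float = 1.0,
) -> PositionTree:
    """Restrict the tree to nodes possessing ``column``.

    ``position_sets`` maps every node label (leaves and ancestors) to its
    set of valid columns.  Nodes lacking the column are removed; an
    included node attaches to its nearest included ancestor with branch
    lengths summed through the removed nodes, and nodes with no included
    ancestor become component tops.
    """
    included = {lbl for lbl, cols in position_sets.items() if column in cols}
    if not included:
        raise EmptyPositionTreeError(f"no node has content at column {column}")
    pnodes: Dict[str, PNode] = {}
    tops: List[PNode] = []
    for node in tree.preorder():
        if node.label not in included:
            continue
        pn = PNode(node.label, node.is_leaf, 0.0)
        pnodes[node.label] = pn
        # walk up to the nearest included ancestor, summing branch lengths
        dist = node.length
        anc = node.parent
        while anc is not None and anc.label not in included:
            dist += anc.length
            anc = anc.parent
        if anc is None:
            pn.length = 0.0
            tops.append(pn)
        else:
            pn.length = dist
            pnodes[anc.label].children.append(pn)
    return PositionTree(column, tops, rate)


# ---------------------------------------------------------------------------
# Joint (max-product) inference
# ---------------------------------------------------------------------------

def joint_reconstruction(
    ptree: PositionTree,
    leaf_chars: Dict[str, str],
    model: SubstitutionModel,
) -> Tuple[Dict[str, str], float]:
    """Most probable joint assignment of ancestor characters at one column.

    Returns ``(states, log_likelihood)`` where ``states`` maps every
    ancestor in the position tree to its character and the log-likelihood
    is that of the maximising assignment (prior included).
    """
    states: Dict[str, str] = {}
    total = 0.0
    for top in ptree.components:
        s, ll = _joint_component(top, leaf_chars, model, ptree.rate)
        states.update(s)
        total += ll
    return states, total


def _joint_component(top: PNode, leaf_chars, model, rate):
    na = len(model.alphabet)
    logpi = np.log(model.pi)
    msg: Dict[str, np.ndarray] = {}
    back: Dict[str, np.ndarray] = {}

    def down(node: PNode) -> None:
        for child in node.children:
            down(child)
        if node is top:
            return
        P = model.transition_probabilities(node.length, rate)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        if node.is_leaf:
            lik = model.char_likelihood(leaf_chars[node.label])
            with np.errstate(divide="ignore"):
                # leaf characters are observed, not maximised: sum over
                # compatible states (relevant only for ambiguity codes)
                msg[node.label] = np.log(P @ lik)
        else:
            inner = np.zeros(na)
            for child in node.children:
                inner += msg[child.label]
            scores = logP + inner[None, :]
            back[node.label] = np.argmax(scores, axis=1)
            msg[node.label] = scores[np.arange(na), back[node.label]]

    down(top)
    states: Dict[str, str] = {}
    if top.is_leaf:
        # singleton component: the leaf is observed, nothing to infer
        lik = model.char_likelihood(leaf_chars[top.label])
        return states, float(np.log(np.dot(model.pi, lik)))
    inner = logpi.copy()
    for child in top.children:
        inner += msg[child.label]
    best = int(np.argmax(inner))            # ties: lowest alphabet index
    states[top.label] = model.alphabet[best]
    loglik = float(inner[best])

    def trace(node: PNode, parent_state: int) -> None:
        for child in node.children:
            if child.is_leaf:
                continue
            s = int(back[child.label][parent_state])
            states[child.label] = model.alphabet[s]
            trace(child, s)

    trace(top, best)
    return states, loglik


# ---------------------------------------------------------------------------
# Marginal (sum-product) inference
# ---------------------------------------------------------------------------

def marginal_reconstruction(
    ptree: PositionTree,
    leaf_chars: Dict[str, str],
    model: SubstitutionModel,
    node_label: str,
) -> np.ndarray:
    """Exact posterior distribution over characters at one ancestor.

    All other unobserved nodes are summed out (inside-outside on the
    component containing the queried ancestor); the result is normalised
    to 1.
    """
    for top in ptree.components:
        result = _marginal_component(top, leaf_chars, model, ptree.rate, node_label)
        if result is not None:
            return result
    raise NodeMissingAtPositionError(
        f"ancestor {node_label!r} has no content at column {ptree.column}"
    )


def _marginal_component(top, leaf_chars, model, rate, query):
    # collect nodes; bail out early if the query is not in this component
    found = False
    order: List[PNode] = []
    stack = [top]
    while stack:
        node = stack.pop()
        order.append(node)
        if node.label == query and not node.is_leaf:
            found = True
        stack.extend(node.children)
    if not found:
        return None
    na = len(model.alphabet)
    inside: Dict[str, np.ndarray] = {}
    Ps: Dict[str, np.ndarray] = {}
    for node in reversed(order):            # postorder
        if node is not top:
            Ps[node.label] = model.transition_probabilities(node.length, rate)
        if node.is_leaf:
            inside[node.label] = model.char_likelihood(leaf_chars[node.label])
        else:
            vec = np.ones(na)
            for child in node.children:
                vec = vec * (Ps[child.label] @ inside[child.label])
            s = vec.sum()
            if s > 0:                        # rescale against underflow
                vec = vec / s
            inside[node.label] = vec
    outside: Dict[str, np.ndarray] = {top.label: model.pi.copy()}
    for node in order:                       # preorder
        if node.is_leaf:
            continue
        up_msgs = {c.label: Ps[c.label] @ inside[c.label] for c in node.children}
        for child in node.children:
            if child.is_leaf:
                continue
            acc = outside[node.label].copy()
            for other in node.children:
                if other is not child:
                    acc = acc * up_msgs[other.label]
            vec = Ps[child.label].T @ acc
            s = vec.sum()
            if s > 0:
                vec = vec / s
            outside[child.label] = vec
    post = outside[query] * inside[query]
    total = post.sum()
    if total <= 0:
        raise PogasrError("marginal posterior underflowed to zero")
    return post / total


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class JointAssignment:
    """Joint-ML characters for every ancestor at its valid positions."""

    states: Dict[str, Dict[int, str]]         # ancestor -> column -> char
    log_likelihood: Dict[int, float]           # column -> max joint log-lik


@dataclass
class MarginalDistribution:
    """Per-position posterior distributions for one queried ancestor."""

    ancestor: str
    alphabet: Tuple[str, ...]
    distributions: Dict[int, np.ndarray]       # column -> probabilities

    def map_state(self, column: int) -> str:
        return self.alphabet[int(np.argmax(self.distributions[column]))]


@dataclass
class Reconstruction:
    """Result of the three-stage pipeline: indel histories, character
    inference, and assembled ancestor POGs."""

    pogs: Dict[str, AncestorPOG]
    joint: Optional[JointAssignment] = None
    marginal: Optional[MarginalDistribution] = None
    components: Dict[int, List[str]] = field(default_factory=dict)


def reconstruct(
    alignment: Alignment,
    tree: PhyloTree,
    option: str = "BE-P",
    model: Optional[SubstitutionModel] = None,
    rates: Optional[RateVector] = None,
    mode: str = "joint",
    node: Optional[str] = None,
    with_no_edge: bool = False,
) -> Reconstruction:
    """Run indel inference then per-column character inference.

    ``mode='joint'`` infers characters for all ancestors; ``mode='marginal'``
    requires ``node`` and attaches posterior distributions to that
    ancestor's POG.
    """
    from .core_model import load_model

    if mode not in ("joint", "marginal"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if mode == "marginal" and node is None:
        raise InvalidParameterError("marginal mode requires an ancestor label")
    model = model or load_model("JTT")
    rates = rates or RateVector.uniform(alignment.n_cols)
    rates.check_length(alignment.n_cols)

    pogs = infer_indels(alignment, tree, option, with_no_edge)
    if node is not None and node not in pogs:
        raise KeyError(f"unknown ancestor label {node!r}")

    position_sets: Dict[str, Set[int]] = {
        sid: set(alignment.content_columns(sid)) for sid in alignment.ids
    }
    for k, pog in pogs.items():
        position_sets[k] = set(pog.positions())

    leaf_chars_by_col: Dict[int, Dict[str, str]] = {}
    for i in range(1, alignment.n_cols + 1):
        leaf_chars_by_col[i] = {
            sid: alignment.row(sid)[i - 1]
            for sid in alignment.ids
            if i in position_sets[sid]
        }

    components: Dict[int, List[str]] = {}
    result = Reconstruction(pogs=pogs, components=components)

    if mode == "joint":
        states: Dict[str, Dict[int, str]] = {k: {} for k in pogs}
        logliks: Dict[int, float] = {}
        for i in range(1, alignment.n_cols + 1):
            if not any(i in position_sets[k] for k in pogs):
                continue
            ptree = build_position_tree(tree, position_sets, i, rates[i])
            components[i] = [t.label for t in ptree.components]
            s, ll = joint_reconstruction(ptree, leaf_chars_by_col[i], model)
            logliks[i] = ll
            for k, char in s.items():
                states[k][i] = char
        for k, pog in pogs.items():
            pog.states = states[k]
        result.joint = JointAssignment(states, logliks)
    else:
        dists: Dict[int, np.ndarray] = {}
        for i in sorted(position_sets[node]):
            ptree = build_position_tree(tree, position_sets, i, rates[i])
            components[i] = [t.label for t in ptree.components]
            dists[i] = marginal_reconstruction(
                ptree, leaf_chars_by_col[i], model, node
            )
        pogs[node].distributions = dists
        result.marginal = MarginalDistribution(node, model.alphabet, dists)
    return result


# ---------------------------------------------------------------------------
# Posterior-guided variant prioritisation
# ---------------------------------------------------------------------------

def rank_alternative_states(
    dist: MarginalDistribution,
    site: int,
    max_k: int,
) -> Dict[str, object]:
    """Rank plausible alternative residues at one site of a marginal
    reconstruction.

    Characters are returned in decreasing posterior order.  For each
    prefix set S of the ranking, the relative entropy D(q_S || p) between
    the posterior truncated and renormalised over S (q_S) and the full
    posterior p is reported; it equals ``-log`` of the posterior mass
    captured by S, so greedily adding the next most probable residue
    minimises it at every set size.  The site's Shannon entropy is
    reported alongside.
    """
    if max_k < 1:
        raise InvalidParameterError("max_k must be >= 1")
    if site not in dist.distributions:
        raise NodeMissingAtPositionError(
            f"site {site} not in ancestor {dist.ancestor!r}"
        )
    p = np.asarray(dist.distributions[site], dtype=float)
    order = sorted(range(len(p)), key=lambda i: (-p[i], dist.alphabet[i]))
    ranked = [(dist.alphabet[i], float(p[i])) for i in order[:max_k]]
    nz = p[p > 0]
    shannon = float(-(nz * np.log2(nz)).sum())
    # D(q_S || p) with q_S = p restricted to S and renormalised reduces to
    # -log(mass of S): the penalty for truncating the distribution to S
    prefix_divergence = []
    mass = 0.0
    for i in order[:max_k]:
        mass += p[i]
        prefix_divergence.append(max(0.0, float(-math.log(min(mass, 1.0)))))
    return {
        "ranking": ranked,
        "prefix_relative_entropy": prefix_divergence,
        "shannon_entropy": shannon,
    }
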