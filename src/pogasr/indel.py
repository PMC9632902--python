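"""Indel-history inference.

Three encodings of the indel signal in an alignment are supported:

* **PS** (position-specific): every column is a binary content/gap
  character, inferred independently at each ancestor.
* **SIC** (simple indel coding): deletions are events identified by their
  start *and* end columns; a sequence is *present* for an event exactly
  matching one of its gap runs, *inapplicable* when the event is strictly
  contained in one of its gap runs, and *absent* otherwise.
* **BE** (bi-directional edge): per reference position the candidate
  right (forward) and left (backward) neighbours drawn from the input
  POG; each edge is scored twice, once per direction, and an edge is
  bi-directionally supported when it is optimal both ways.

Each encoding can be resolved over the tree by maximum parsimony or by
joint maximum likelihood under a uniform (Jukes-Cantor-style) model with
as many states as the encoding requires, giving the six options
PS-P, PS-ML, SIC-P, SIC-ML, BE-P and BE-ML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core_model import (
    Alignment,
    ConsistencyError,
    InvalidParameterError,
    PhyloTree,
    PogasrError,
)
from .pog import AncestorPOG, ExtantPOG, InputPOG, build_extant_pog, build_input_pog

INDEL_OPTIONS = ("BE-P", "BE-ML", "SIC-P", "SIC-ML", "PS-P", "PS-ML")

#: Cost standing in for -ln(0) at extant leaves; any assignment whose total
#: reaches this magnitude is infeasible.
INFEASIBLE = 1e9

#: Distinguished "no edge" competitor state for the BE encodings.
NO_EDGE = -1


class UnsupportedOptionError(PogasrError, ValueError):
    pass


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------

@dataclass
class IndelEvent:
    """An insertion or deletion on a specific branch.

    ``branch`` names the child node of the branch; ``start``/``end`` are
    the first and last affected alignment columns (1-based, inclusive).
    The flanking-edge form ``(start - 1, end + 1)`` names the POG edge
    that skips the event.
    """

    branch: str
    kind: str                      # "insertion" | "deletion"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise InvalidParameterError(f"bad event kind {self.kind!r}")
        if not self.start <= self.end:
            raise InvalidParameterError("event start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def edge(self) -> Tuple[int, int]:
        return (self.start - 1, self.end + 1)

    def key(self) -> Tuple[str, int, int]:
        """Identity used when matching events: branch + start + end."""
        return (self.branch, self.start, self.end)


@dataclass
class PSEncoding:
    method: str
    content: np.ndarray            # (M, N) boolean: True where content


@dataclass
class SICEncoding:
    method: str
    events: List[Tuple[int, int]]                      # (start, end) columns
    states: Dict[Tuple[int, int], List[str]]           # per-sequence state


@dataclass
class BEEncoding:
    method: str
    with_no_edge: bool
    input_pog: InputPOG
    forward: Dict[int, List[int]]                      # position -> candidates
    backward: Dict[int, List[int]]


def gap_runs(row: str, gap_char: str = "-") -> List[Tuple[int, int]]:
    """Maximal gap runs of a row as (start, end) 1-based column ranges."""
    runs: List[Tuple[int, int]] = []
    start = None
    for i, c in enumerate(row, start=1):
        if c == gap_char and start is None:
            start = i
        elif c != gap_char and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def encode_indels(alignment: Alignment, method: str, with_no_edge: bool = False):
    """Build the PS, SIC or BE encoding of the alignment's indel signal."""
    method = method.upper()
    if method == "PS":
        content = np.array(
            [[c != alignment.gap_char for c in row] for row in alignment.rows],
            dtype=bool,
        )
        return PSEncoding(method, content)
    if method == "SIC":
        per_seq_runs = [gap_runs(row, alignment.gap_char) for row in alignment.rows]
        events = sorted({run for runs in per_seq_runs for run in runs})
        states: Dict[Tuple[int, int], List[str]] = {}
        for ev in events:
            s, e = ev
            col: List[str] = []
            for runs in per_seq_runs:
                if ev in runs:
                    col.append("present")
                elif any(rs <= s and e <= re and (rs < s or e < re)
                         for rs, re in runs):
                    col.append("inapplicable")
                else:
                    col.append("absent")
            states[ev] = col
        return SICEncoding(method, events, states)
    if method == "BE":
        input_pog = build_input_pog(alignment)
        n = alignment.n_cols
        forward = {i: input_pog.next_nodes(i) for i in range(0, n + 1)
                   if input_pog.next_nodes(i)}
        backward = {i: input_pog.prev_nodes(i) for i in range(1, n + 2)
                    if input_pog.prev_nodes(i)}
        if with_no_edge:
            present = _presence_matrix(alignment)
            any_missing = ~present.all(axis=0)
            for i in list(forward):
                if 1 <= i <= n and any_missing[i - 1]:
                    forward[i] = forward[i] + [NO_EDGE]
            for i in list(backward):
                if 1 <= i <= n and any_missing[i - 1]:
                    backward[i] = backward[i] + [NO_EDGE]
        return BEEncoding(method, with_no_edge, input_pog, forward, backward)
    raise UnsupportedOptionError(f"unknown encoding {method!r}")


def _presence_matrix(alignment: Alignment) -> np.ndarray:
    return np.array(
        [[c != alignment.gap_char for c in row] for row in alignment.rows],
        dtype=bool,
    )


# ---------------------------------------------------------------------------
# Discrete-state history inference on the tree (shared engine)
# ---------------------------------------------------------------------------

def infer_discrete_history(
    tree: PhyloTree,
    leaf_states: Dict[str, Optional[Hashable]],
    mode: str,
    state_set: Optional[Sequence[Hashable]] = None,
) -> Tuple[Dict[str, FrozenSet[Hashable]], float]:
    """Infer per-ancestor states for one discrete character on the tree.

    ``leaf_states`` maps every leaf label to a state or to ``None``
    (missing data).  Parsimony returns, per ancestor, the set of states
    attaining the minimum total number of changes (Sankoff with unit
    costs); a state is reported iff it occurs in at least one globally
    optimal assignment.  ML returns the joint maximum-likelihood states
    under a uniform reversible model with ``len(state_set)`` symbols and
    the tree's branch lengths, ties (within 1e-9 in log likelihood)
    reported as sets.

    Returns ``(ancestor_states, score)`` where score is the minimum cost
    (parsimony) or the maximum joint log-likelihood (ML).
    """
    if state_set is None:
        observed = {s for s in leaf_states.values() if s is not None}
        state_set = sorted(observed)
    states = list(state_set)
    for leaf in tree.leaf_labels:
        if leaf not in leaf_states:
            raise InvalidParameterError(f"no state supplied for leaf {leaf!r}")
        s = leaf_states[leaf]
        if s is not None and s not in states:
            raise InvalidParameterError(f"leaf state {s!r} outside the state set")
    if not states:
        return {k: frozenset() for k in tree.ancestor_labels}, 0.0
    if mode == "parsimony":
        return _sankoff(tree, leaf_states, states)
    if mode == "ML":
        return _joint_ml_uniform(tree, leaf_states, states)
    raise UnsupportedOptionError(f"unknown inference mode {mode!r}")


def _sankoff(tree, leaf_states, states):
    """Small parsimony with unit substitution costs and set-valued traceback."""
    ns = len(states)
    index = {s: i for i, s in enumerate(states)}
    cost: Dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(ns) if leaf_states[node.label] is None else \
                np.full(ns, INFEASIBLE)
            if leaf_states[node.label] is not None:
                vec[index[leaf_states[node.label]]] = 0.0
            cost[node.label] = vec
        else:
            total = np.zeros(ns)
            for child in node.children:
                c = cost[child.label]
                # unit-cost Delta: min over child state = min(keep, change+1)
                total += np.minimum(c, c.min() + 1.0)
            cost[node.label] = total
    root_cost = cost[tree.root.label]
    best = root_cost.min()
    chosen: Dict[str, FrozenSet] = {
        tree.root.label: frozenset(
            states[i] for i in np.nonzero(root_cost == best)[0]
        )
    }
    for node in tree.preorder():
        if node.is_leaf or node.label not in chosen:
            continue
        for child in node.children:
            if child.is_leaf:
                continue
            c = cost[child.label]
            picks: Set = set()
            for s in chosen[node.label]:
                i = index[s]
                stay = c[i]
                move = c.min() + 1.0
                m = min(stay, move)
                if stay == m:
                    picks.add(s)
                if move == m:
                    picks.update(states[j] for j in np.nonzero(c == c.min())[0])
            chosen.setdefault(child.label, frozenset())
            chosen[child.label] = chosen[child.label] | frozenset(picks)
    return chosen, float(best)


def _uniform_logP(n: int, d: float) -> Tuple[float, float]:
    """(log P_same, log P_diff) for the n-state uniform model at distance d,
    normalised to one expected change per unit time."""
    if n == 1:
        return 0.0, -math.inf
    e = math.exp(-n * d / (n - 1))
    p_same = 1.0 / n + (n - 1) / n * e
    p_diff = (1.0 - e) / n
    return math.log(p_same), math.log(p_diff) if p_diff > 0 else -INFEASIBLE


def _joint_ml_uniform(tree, leaf_states, states, tie_tol: float = 1e-9):
    """Joint ML under the uniform model via max-product with traceback."""
    ns = len(states)
    index = {s: i for i, s in enumerate(states)}
    # message[child] (s_parent) = log max over child subtree given parent state
    msg: Dict[str, np.ndarray] = {}
    argmax: Dict[str, List[List[int]]] = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        d = node.length
        ls, ld = _uniform_logP(ns, d)
        if node.is_leaf:
            obs = leaf_states[node.label]
            if obs is None:
                # missing data sums to 1 regardless of the parent state
                msg[node.label] = np.zeros(ns)
            else:
                vec = np.full(ns, ld)
                vec[index[obs]] = ls
                msg[node.label] = vec
        else:
            inner = np.zeros(ns)
            for child in node.children:
                inner += msg[child.label]
            # m(sp) = max_s logP(sp -> s) + inner(s)
            out = np.empty(ns)
            arg: List[List[int]] = []
            for ip in range(ns):
                scores = inner + ld
                scores[ip] = inner[ip] + ls
                best = scores.max()
                out[ip] = best
                arg.append(list(np.nonzero(scores >= best - tie_tol)[0]))
            msg[node.label] = out
            argmax[node.label] = arg
    # root: uniform prior over states (constant), maximise the product
    inner = np.zeros(ns)
    for child in tree.root.children:
        inner += msg[child.label]
    best = inner.max()
    chosen: Dict[str, FrozenSet] = {
        tree.root.label: frozenset(
            states[i] for i in np.nonzero(inner >= best - tie_tol)[0]
        )
    }
    for node in tree.preorder():
        if node.is_leaf or node.label not in chosen:
            continue
        for child in node.children:
            if child.is_leaf:
                continue
            picks: Set = set()
            for s in chosen[node.label]:
                for j in argmax[child.label][index[s]]:
                    picks.add(states[j])
            chosen[child.label] = frozenset(picks)
    loglik = float(best) - math.log(ns)      # include the uniform root prior
    return chosen, loglik


# ---------------------------------------------------------------------------
# Bi-directional edge inference
# ---------------------------------------------------------------------------

def be_parsimony(
    tree: PhyloTree,
    extant_pogs: Dict[str, ExtantPOG],
    input_pog: InputPOG,
    with_no_edge: bool = False,
) -> Dict[str, np.ndarray]:
    """Bi-directional edge parsimony: per-ancestor support matrices.

    For every reference position and direction independently, a
    small-parsimony problem is solved over the tree whose states are the
    candidate neighbours drawn from the input POG: retaining the child's
    edge is cost-free and switching to a different edge costs 1, with
    extant sequences forcing their own edges (cost 0 or effectively
    infinity).  All co-optimal traced choices are recorded, forward
    support above the diagonal and backward support below it.
    """
    return _be_infer(tree, extant_pogs, input_pog, "parsimony", with_no_edge)


def be_ml(
    tree: PhyloTree,
    extant_pogs: Dict[str, ExtantPOG],
    input_pog: InputPOG,
    with_no_edge: bool = False,
) -> Dict[str, np.ndarray]:
    """Bi-directional edge inference by joint ML under uniform models with
    as many states as there are candidate neighbours at each position."""
    return _be_infer(tree, extant_pogs, input_pog, "ML", with_no_edge)


def _be_infer(tree, extant_pogs, input_pog, mode, with_no_edge):
    if set(extant_pogs) != set(tree.leaf_labels):
        raise ConsistencyError("extant POGs do not match the tree's leaves")
    n = input_pog.n_cols
    end = n + 1
    forward = {k: np.zeros((n + 2, n + 2), dtype=bool)
               for k in tree.ancestor_labels}
    backward = {k: np.zeros((n + 2, n + 2), dtype=bool)
                for k in tree.ancestor_labels}

    # per-leaf neighbour lookups along each extant chain
    nxt: Dict[str, Dict[int, int]] = {}
    prv: Dict[str, Dict[int, int]] = {}
    for sid, pog in extant_pogs.items():
        chain = [0] + pog.positions + [end]
        nxt[sid] = {a: b for a, b in zip(chain[:-1], chain[1:])}
        prv[sid] = {b: a for a, b in zip(chain[:-1], chain[1:])}

    # ancestors whose subtree contains >= 1 extant with the position; the
    # legacy handling excludes the reference position elsewhere
    has_pos = _subtree_presence(tree, extant_pogs, n)

    for direction in ("forward", "backward"):
        lookup = nxt if direction == "forward" else prv
        if direction == "forward":
            ref_positions = [i for i in range(0, end)
                             if input_pog.next_nodes(i)]
        else:
            ref_positions = [i for i in range(1, end + 1)
                             if input_pog.prev_nodes(i)]
        for i in ref_positions:
            if direction == "forward":
                candidates = list(input_pog.next_nodes(i))
            else:
                candidates = list(input_pog.prev_nodes(i))
            terminal = i == 0 or i == end
            missing_somewhere = any(i not in lookup[sid]
                                    for sid in tree.leaf_labels)
            if with_no_edge and missing_somewhere and not terminal:
                candidates = candidates + [NO_EDGE]
            leaf_states: Dict[str, Optional[int]] = {}
            for sid in tree.leaf_labels:
                if i in lookup[sid]:
                    leaf_states[sid] = lookup[sid][i]
                else:
                    # legacy: missing data; no-edge mode: observed "no edge"
                    leaf_states[sid] = NO_EDGE if (with_no_edge and not terminal) \
                        else None
            chosen, _ = infer_discrete_history(tree, leaf_states, mode,
                                               state_set=candidates)
            target = forward if direction == "forward" else backward
            for k, picks in chosen.items():
                for b in picks:
                    if b != NO_EDGE:
                        target[k][i, b] = True

    # Legacy missing-data handling: a reference position whose entire
    # extant subtree lacks content is excluded at that ancestor — the
    # ancestor's sequence skips it, so traced edges through excluded
    # nodes are contracted into bridging edges.
    support = {}
    for k in tree.ancestor_labels:
        if not with_no_edge:
            excluded = np.zeros(n + 2, dtype=bool)
            excluded[1:n + 1] = ~has_pos[k]
            fwd = _contract_excluded(forward[k], excluded)
            bwd = _contract_excluded(backward[k], excluded)
        else:
            fwd, bwd = forward[k], backward[k]
        S = np.zeros((n + 2, n + 2), dtype=np.int8)
        S[fwd] = 1
        S[bwd] = 1      # backward entries are below the diagonal already
        support[k] = S
    return support


def _contract_excluded(adj: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Bypass excluded nodes: edge (a, b) between kept nodes iff the
    original graph has a path a -> ... -> b through excluded nodes only."""
    X = np.nonzero(excluded)[0]
    if X.size == 0 or not adj.any():
        return adj
    K = np.nonzero(~excluded)[0]
    A_XX = adj[np.ix_(X, X)]
    # reachability closure within the excluded set (length >= 0 paths)
    C = np.eye(len(X), dtype=bool)
    frontier = C
    while True:
        frontier = (frontier.astype(np.int32) @ A_XX.astype(np.int32)) > 0
        new = frontier & ~C
        if not new.any():
            break
        C |= new
    bridged = (adj[np.ix_(K, X)].astype(np.int32)
               @ C.astype(np.int32)
               @ adj[np.ix_(X, K)].astype(np.int32)) > 0
    out = np.zeros_like(adj)
    out[np.ix_(K, K)] = adj[np.ix_(K, K)] | bridged
    return out


def _subtree_presence(tree, extant_pogs, n) -> Dict[str, np.ndarray]:
    """For each ancestor, a boolean vector over columns: does any extant in
    its subtree have content there?"""
    out: Dict[str, np.ndarray] = {}
    leaf_vec = {}
    for sid, pog in extant_pogs.items():
        v = np.zeros(n, dtype=bool)
        for i in pog.positions:
            v[i - 1] = True
        leaf_vec[sid] = v
    for node in tree.postorder():
        if node.is_leaf:
            continue
        v = np.zeros(n, dtype=bool)
        for child in node.children:
            v |= leaf_vec[child.label] if child.is_leaf else out[child.label]
        out[node.label] = v
    return out


# ---------------------------------------------------------------------------
# PS / SIC to ancestor position states
# ---------------------------------------------------------------------------

def _ps_ancestor_states(alignment, tree, mode):
    """Per-ancestor tri-state per column: 'present', 'absent' or 'tied'."""
    enc = encode_indels(alignment, "PS")
    n = alignment.n_cols
    out = {k: ["absent"] * n for k in tree.ancestor_labels}
    for col in range(n):
        leaf_states = {
            sid: ("content" if enc.content[alignment.index_of(sid), col] else "gap")
            for sid in tree.leaf_labels
        }
        chosen, _ = infer_discrete_history(tree, leaf_states, mode,
                                           state_set=["content", "gap"])
        for k, picks in chosen.items():
            if picks == frozenset({"content"}):
                out[k][col] = "present"
            elif "content" in picks:
                out[k][col] = "tied"
    return out


def _sic_ancestor_states(alignment, tree, mode):
    enc = encode_indels(alignment, "SIC")
    n = alignment.n_cols
    # start from all-present; deletions inferred present knock columns out
    out = {k: ["present"] * n for k in tree.ancestor_labels}
    for ev in enc.events:
        s, e = ev
        leaf_states: Dict[str, Optional[str]] = {}
        for sid in tree.leaf_labels:
            st = enc.states[ev][alignment.index_of(sid)]
            leaf_states[sid] = None if st == "inapplicable" else st
        chosen, _ = infer_discrete_history(tree, leaf_states, mode,
                                           state_set=["absent", "present"])
        for k, picks in chosen.items():
            if picks == frozenset({"present"}):
                for col in range(s - 1, e):
                    out[k][col] = "absent"
            elif "present" in picks:
                for col in range(s - 1, e):
                    if out[k][col] != "absent":
                        out[k][col] = "tied"
    return out


def _tristate_to_support(states: Sequence[str], n: int) -> np.ndarray:
    """Connect present columns into a chain, with tied columns optional.

    From any node, edges run to every tied column before the next definite
    column and to that definite column itself, so each subset of a tied
    run yields a valid path.  All edges are recorded in both directions.
    """
    support = np.zeros((n + 2, n + 2), dtype=np.int8)
    nodes = [0] + [i + 1 for i, s in enumerate(states) if s != "absent"] + [n + 1]
    definite = {0, n + 1} | {i + 1 for i, s in enumerate(states) if s == "present"}
    for idx, u in enumerate(nodes[:-1]):
        for v in nodes[idx + 1:]:
            support[u, v] = 1
            support[v, u] = 1
            if v in definite:
                break
    return support


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def infer_indels(
    alignment: Alignment,
    tree: PhyloTree,
    option: str = "BE-P",
    with_no_edge: bool = False,
) -> Dict[str, AncestorPOG]:
    """Infer every ancestor's POG skeleton under one of the six options.

    The returned POGs are pruned so every retained node lies on a
    complete 0 -> N+1 path; co-optimal (tied) histories are retained as
    parallel edges and paths.
    """
    option = option.upper()
    if option not in INDEL_OPTIONS:
        raise UnsupportedOptionError(
            f"unknown indel option {option!r}; choose from {INDEL_OPTIONS}"
        )
    tree.check_against_alignment(alignment)
    n = alignment.n_cols
    encoding, mode = option.split("-")
    mode = "parsimony" if mode == "P" else "ML"
    if encoding == "BE":
        extant_pogs = {sid: build_extant_pog(alignment, sid)
                       for sid in alignment.ids}
        input_pog = build_input_pog(alignment)
        support = _be_infer(tree, extant_pogs, input_pog, mode, with_no_edge)
    else:
        states = (_ps_ancestor_states if encoding == "PS"
                  else _sic_ancestor_states)(alignment, tree, mode)
        support = {k: _tristate_to_support(v, n) for k, v in states.items()}
    pogs = {}
    for k in tree.ancestor_labels:
        pog = AncestorPOG(k, n, support[k])
        pog.prune_to_paths()
        pogs[k] = pog
    return pogs


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

def extract_indel_events(
    parent_positions: Sequence[int],
    child_positions: Sequence[int],
    branch: str,
) -> List[IndelEvent]:
    """Indel events on the branch to ``branch``, from its parent's and its
    own position sets.

    A deletion is a maximal run of parent positions that the child lacks,
    uninterrupted by any column the child possesses (columns absent from
    both sequences — e.g. content private to other lineages — do not
    split a run); an insertion is the converse.  Coordinates are
    alignment column ranges (the flanking-edge form is available on the
    event).
    """
    parent = list(parent_positions)
    child_set = set(child_positions)
    events: List[IndelEvent] = []
    events += _runs(parent, child_set, branch, "deletion")
    events += _runs(list(child_positions), set(parent), branch, "insertion")
    return sorted(events, key=lambda e: (e.start, e.end, e.kind))


def _runs(positions, other_set, branch, kind):
    events = []
    run: List[int] = []
    for p in positions:
        if p not in other_set:
            if run and any(c in other_set for c in range(run[-1] + 1, p)):
                events.append(IndelEvent(branch, kind, run[0], run[-1]))
                run = []
            run.append(p)
        elif run:
            events.append(IndelEvent(branch, kind, run[0], run[-1]))
            run = []
    if run:
        events.append(IndelEvent(branch, kind, run[0], run[-1]))
    return events
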