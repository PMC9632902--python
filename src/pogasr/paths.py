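"""Reduce an ancestor POG to a single preferred sequence.

Edges are weighted by the proportion of extant sequences *under the
ancestor* that contain them; the preferred path minimises

    gamma(a, b) = (1 + eta(a, b) * (1 - w(a, b))) * (b - a)

over a complete 0 -> N+1 path, where eta = N for a non-terminal
uni-directional edge and 1 otherwise, so uni-directional edges are only
used when no bi-directional alternative completes the traversal, and the
(b - a) factor scores every complete sequence evenly regardless of how
many edges compose it.  The search is A* with the admissible heuristic
h(a) = N + 1 - a (every edge costs at least b - a).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_model import ConsistencyError, PhyloTree, PogasrError
from .pog import AncestorPOG, DisconnectedPOGError, ExtantPOG


@dataclass
class PreferredPath:
    """A single complete path through an ancestor POG."""

    ancestor: str
    nodes: List[int]                       # 0 = p0 < ... < N+1
    cost: float
    edge_costs: List[float]
    bidirectional: List[bool]
    sequence: str = ""

    @property
    def positions(self) -> List[int]:
        return self.nodes[1:-1]

    def __len__(self) -> int:
        return len(self.positions)


def edge_weights(
    tree: PhyloTree,
    extant_pogs: Dict[str, ExtantPOG],
    k: str,
) -> Dict[Tuple[int, int], float]:
    """w_k(a, b): fraction of the extants under ancestor ``k`` whose chain
    contains edge (a, b).  Extants outside the subtree do not count."""
    subtree = tree.subtree_leaves(k)
    if not subtree:
        raise ConsistencyError(f"ancestor {k!r} has no extant descendants")
    counts: Dict[Tuple[int, int], int] = {}
    for sid in subtree:
        for edge in extant_pogs[sid].edges:
            counts[edge] = counts.get(edge, 0) + 1
    m = len(subtree)
    return {edge: c / m for edge, c in counts.items()}


def edge_cost(
    a: int,
    b: int,
    weight: float,
    support_sum: int,
    n_cols: int,
) -> float:
    """gamma for one edge; eta = N for non-terminal uni-directional edges."""
    terminal = a == 0 or b == n_cols + 1
    eta = 1.0 if (support_sum >= 2 or terminal) else float(n_cols)
    return (1.0 + eta * (1.0 - weight)) * (b - a)


def preferred_path(
    pog: AncestorPOG,
    weights: Dict[Tuple[int, int], float],
    states: Optional[Dict[int, str]] = None,
) -> PreferredPath:
    """Minimum-cost complete path by A*; exact, deterministic.

    Ties are broken by the lexicographically smallest node sequence.
    Edges absent from ``weights`` have weight 0.
    """
    n = pog.n_cols
    end = n + 1
    out_edges = _out_edges(pog)
    if not out_edges.get(0):
        raise DisconnectedPOGError("POG has no start edges")

    # A* from 0 to N+1; heuristic h(a) = end - a is admissible and
    # consistent because gamma(a,b) >= b - a.
    best: Dict[int, Tuple[float, Tuple[int, ...]]] = {0: (0.0, (0,))}
    heap: List[Tuple[float, Tuple[int, ...], int]] = [(float(end), (0,), 0)]
    while heap:
        f, path, node = heapq.heappop(heap)
        g, bpath = best[node]
        if path != bpath:
            continue                      # stale entry
        if node == end:
            return _finish(pog, list(path), weights, states)
        for b in out_edges.get(node, ()):
            w = weights.get((node, b), 0.0)
            cost = edge_cost(node, b, w, pog.edge_support_sum(node, b), n)
            cand_g = g + cost
            cand_path = path + (b,)
            if b not in best or cand_g < best[b][0] - 1e-12 or (
                abs(cand_g - best[b][0]) <= 1e-12 and cand_path < best[b][1]
            ):
                best[b] = (cand_g, cand_path)
                heapq.heappush(heap, (cand_g + (end - b), cand_path, b))
    raise DisconnectedPOGError(f"no complete path through POG {pog.label!r}")


def _out_edges(pog: AncestorPOG) -> Dict[int, List[int]]:
    combined = pog.combined_matrix()
    out: Dict[int, List[int]] = {}
    for a, b in zip(*np.nonzero(combined)):
        out.setdefault(int(a), []).append(int(b))
    for v in out.values():
        v.sort()
    return out


def _finish(pog, nodes, weights, states) -> PreferredPath:
    n = pog.n_cols
    costs: List[float] = []
    bidir: List[bool] = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        ssum = pog.edge_support_sum(a, b)
        costs.append(edge_cost(a, b, weights.get((a, b), 0.0), ssum, n))
        bidir.append(ssum >= 2)
    seq = ""
    if states is not None:
        seq = "".join(states[p] for p in nodes[1:-1])
    elif pog.states:
        seq = "".join(pog.states.get(p, "X") for p in nodes[1:-1])
    return PreferredPath(pog.label, nodes, float(sum(costs)), costs, bidir, seq)


def most_probable_path(
    pog: AncestorPOG,
    weights: Dict[Tuple[int, int], float],
    states: Optional[Dict[int, str]] = None,
) -> PreferredPath:
    """Markov-chain style extractor: maximise the sum of log weights.

    At every node, traversal is restricted to bi-directional out-edges
    whenever at least one exists; uni-directional edges are admissible
    only where no bi-directional edge leaves the node.  Zero-weight
    admissible edges fall back to a uniform (heavily penalised) choice
    with a warning.
    """
    n = pog.n_cols
    end = n + 1
    out_edges = _out_edges(pog)
    admissible: Dict[int, List[int]] = {}
    for a, succs in out_edges.items():
        bi = [b for b in succs if pog.edge_support_sum(a, b) >= 2]
        admissible[a] = bi if bi else succs
    warned = False
    for a, succs in admissible.items():
        if succs and all(weights.get((a, b), 0.0) == 0.0 for b in succs):
            if not warned:
                warnings.warn(
                    "node with only zero-weight admissible edges; "
                    "falling back to a uniform choice",
                    stacklevel=2,
                )
                warned = True

    def logw(a: int, b: int) -> float:
        w = weights.get((a, b), 0.0)
        return float(np.log(w)) if w > 0 else -1e9

    # longest-path DP on the DAG restricted to admissible edges, iterating
    # nodes in index (= topological) order
    nodes = sorted(set([0, end]) | {x for a, ss in admissible.items()
                                    for x in [a] + ss})
    bestpath: Dict[int, Tuple[float, Tuple[int, ...]]] = {0: (0.0, (0,))}
    for a in nodes:
        if a not in bestpath:
            continue
        g, path = bestpath[a]
        for b in admissible.get(a, ()):
            cand = (g + logw(a, b), path + (b,))
            if b not in bestpath or cand[0] > bestpath[b][0] + 1e-12 or (
                abs(cand[0] - bestpath[b][0]) <= 1e-12
                and cand[1] < bestpath[b][1]
            ):
                bestpath[b] = cand
    if end not in bestpath:
        # the bi-directional restriction dead-ended; admit all edges
        warnings.warn(
            "bi-directional restriction leaves no complete path; "
            "admitting uni-directional edges everywhere",
            stacklevel=2,
        )
        bestpath = {0: (0.0, (0,))}
        for a in nodes:
            if a not in bestpath:
                continue
            g, path = bestpath[a]
            for b in out_edges.get(a, ()):
                cand = (g + logw(a, b), path + (b,))
                if b not in bestpath or cand[0] > bestpath[b][0]:
                    bestpath[b] = cand
        if end not in bestpath:
            raise DisconnectedPOGError(
                f"no complete path through POG {pog.label!r}"
            )
    return _finish(pog, list(bestpath[end][1]), weights, states)


def emit_sequence(
    path: PreferredPath,
    states: Dict[int, str],
    n_cols: int,
    gap_char: str = "-",
) -> Tuple[str, str]:
    """Concatenate characters along the path.

    Returns ``(ungapped, aligned)`` where the aligned form places each
    character at its alignment column and gaps elsewhere.
    """
    missing = [p for p in path.positions if p not in states]
    if missing:
        raise PogasrError(f"no character state at path positions {missing}")
    aligned = [gap_char] * n_cols
    for p in path.positions:
        aligned[p - 1] = states[p]
    ungapped = "".join(states[p] for p in path.positions)
    return ungapped, "".join(aligned)
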