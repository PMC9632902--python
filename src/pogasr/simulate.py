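"""Sequence-evolution simulation with tracked indel histories, and the
evaluation harness for indel-recovery benchmarks.

Sequences evolve from a root sequence down a (random or supplied) rooted
tree: substitutions follow an empirical amino-acid model with the branch
length as expected substitutions per site, and insertion/deletion events
arrive as a Poisson process at a configurable rate relative to
substitutions, with lengths drawn from a truncated Zipfian distribution.
A global homology column space is maintained throughout, so the true
alignment of every ancestor and leaf is exact and every indel event can
be tied to its branch and column range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core_model import (
    Alignment,
    ConsistencyError,
    InvalidParameterError,
    PhyloTree,
    PogasrError,
    SubstitutionModel,
    TreeNode,
    load_model,
)
from .indel import IndelEvent, extract_indel_events


@dataclass
class SimulationConfig:
    """Study conditions for one simulated reconstruction benchmark.

    Defaults mirror a standard indel-simulation protocol: a Zipfian
    indel-length law with alpha 1.7 truncated at 10, the LG model, unit
    evolutionary depth (expected root-to-tip substitutions), and an indel
    rate expressed relative to the substitution rate.
    """

    taxon_count: int = 100
    root_length: int = 300
    indel_rate: float = 0.01
    zipf_alpha: float = 1.7
    max_indel_length: int = 10
    model_name: str = "LG"
    tree_depth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.indel_rate < 0:
            raise InvalidParameterError("indel_rate must be >= 0")
        if self.zipf_alpha <= 1:
            raise InvalidParameterError("zipf_alpha must be > 1")
        if self.max_indel_length < 1:
            raise InvalidParameterError("max_indel_length must be >= 1")
        if self.root_length < 1:
            raise InvalidParameterError("root_length must be >= 1")
        if self.taxon_count < 2:
            raise InvalidParameterError("taxon_count must be >= 2")


@dataclass
class SimulationResult:
    """Tree, true alignments at all nodes, and the per-branch event log."""

    tree: PhyloTree
    alignment: Alignment                     # extant rows
    ancestral_alignment: Alignment           # ancestor rows, same columns
    events: List[IndelEvent]                 # truth, in final column space
    substitutions: Dict[str, List[Tuple[int, str, str]]] = field(
        default_factory=dict
    )                                        # branch -> (column, from, to)
    config: Optional[SimulationConfig] = None

    def row(self, label: str) -> str:
        if label in set(self.alignment.ids):
            return self.alignment.row(label)
        return self.ancestral_alignment.row(label)

    def positions(self, label: str) -> List[int]:
        gap = self.alignment.gap_char
        return [i + 1 for i, c in enumerate(self.row(label)) if c != gap]


def sample_indel_length(alpha: float, max_len: int, rng: np.random.Generator) -> int:
    """Draw a length from the truncated Zipfian law P(l) ~ l^(-alpha)."""
    if alpha <= 1 or max_len < 1:
        raise InvalidParameterError("require alpha > 1 and max_len >= 1")
    ls = np.arange(1, max_len + 1, dtype=float)
    p = ls ** (-alpha)
    p /= p.sum()
    return int(rng.choice(np.arange(1, max_len + 1), p=p))


def random_tree(
    n_taxa: int,
    depth: float,
    rng: np.random.Generator,
) -> PhyloTree:
    """A random bifurcating tree rescaled to the requested mean depth.

    Topology and branch lengths follow a Yule (pure-birth) process; all
    branch lengths are then scaled so the mean root-to-tip path length
    equals ``depth``.
    """
    tips: List[TreeNode] = [TreeNode(f"s{i + 1}") for i in range(n_taxa)]
    # coalescent-style assembly of a Yule topology with exponential waits
    active = list(tips)
    heights = {id(t): 0.0 for t in tips}
    h = 0.0
    while len(active) > 1:
        k = len(active)
        h += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        parent = TreeNode()
        a.length = h - heights[id(a)]
        b.length = h - heights[id(b)]
        parent.add_child(a)
        parent.add_child(b)
        heights[id(parent)] = h
        active.append(parent)
    root = active[0]
    tree = PhyloTree(root)
    # rescale to the requested evolutionary depth
    depths = []
    for leaf in tips:
        d = 0.0
        node = leaf
        while node.parent is not None:
            d += node.length
            node = node.parent
        depths.append(d)
    mean_depth = float(np.mean(depths))
    if mean_depth > 0:
        factor = depth / mean_depth
        for node in tree.preorder():
            node.length *= factor
    return tree


def simulate_history(
    config: SimulationConfig,
    tree: Optional[PhyloTree] = None,
) -> SimulationResult:
    """Evolve a root sequence down the tree, tracking every indel event.

    Insertion content is drawn from the model's stationary distribution;
    the number of indel events on a branch is Poisson with intensity
    ``indel_rate * branch_length * current_sequence_length``, split
    evenly between insertions and deletions.  Entirely extant-empty
    columns are stripped from both the extant and ancestral alignments
    (with event coordinates remapped); events that vanish with those
    columns are dropped from the log.
    """
    rng = np.random.default_rng(config.seed)
    model = load_model(config.model_name)
    if tree is None:
        tree = random_tree(config.taxon_count, config.tree_depth, rng)

    # Global homology columns carry stable ids; each node's row is a dict
    # col_id -> amino acid.  Insertions splice new ids into the order.
    col_order: List[int] = list(range(config.root_length))
    next_id = config.root_length
    alphabet = list(model.alphabet)
    root_seq = rng.choice(len(alphabet), size=config.root_length, p=model.pi)
    rows: Dict[str, Dict[int, str]] = {
        tree.root.label: {c: alphabet[root_seq[c]] for c in col_order}
    }
    raw_events: List[Tuple[str, str, List[int]]] = []   # (branch, kind, col ids)
    substitutions: Dict[str, List[Tuple[int, str, str]]] = {}

    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_row = rows[node.parent.label]
        row = dict(parent_row)
        d = node.length
        subs: List[Tuple[int, str, str]] = []
        if d > 0:
            P = model.transition_probabilities(d)
            cum = np.cumsum(P, axis=1)
            for cid in list(row):
                a = model.index(row[cid])
                u = rng.random()
                b = int(np.searchsorted(cum[a], u))
                if b != a:
                    subs.append((cid, alphabet[a], alphabet[b]))
                    row[cid] = alphabet[b]
        # indel events on this branch
        n_events = rng.poisson(config.indel_rate * d * max(len(row), 1)) \
            if config.indel_rate > 0 and d > 0 else 0
        for _ in range(n_events):
            length = sample_indel_length(config.zipf_alpha,
                                         config.max_indel_length, rng)
            present = [c for c in col_order if c in row]
            if rng.random() < 0.5 and present:
                # deletion: start uniform over residues, truncated at the end
                start = int(rng.integers(len(present)))
                victims = present[start:start + length]
                for c in victims:
                    del row[c]
                raw_events.append((node.label, "deletion", victims))
            else:
                # insertion: slot uniform over len+1 positions
                slot = int(rng.integers(len(present) + 1))
                if slot == 0:
                    order_idx = 0 if not present else col_order.index(present[0])
                else:
                    order_idx = col_order.index(present[slot - 1]) + 1
                new_ids = list(range(next_id, next_id + length))
                next_id += length
                col_order[order_idx:order_idx] = new_ids
                content = rng.choice(len(alphabet), size=length, p=model.pi)
                for cid, a in zip(new_ids, content):
                    row[cid] = alphabet[int(a)]
                raw_events.append((node.label, "insertion", new_ids))
        substitutions[node.label] = subs
        rows[node.label] = row

    # strip columns with no extant content anywhere
    leaf_labels = set(tree.leaf_labels)
    occupied: Set[int] = set()
    for lbl in leaf_labels:
        occupied.update(rows[lbl])
    kept = [c for c in col_order if c in occupied]
    col_index = {c: i + 1 for i, c in enumerate(kept)}     # 1-based columns

    def to_row(label: str) -> str:
        r = rows[label]
        return "".join(r.get(c, "-") for c in kept)

    alignment = Alignment(list(tree.leaf_labels),
                          [to_row(lbl) for lbl in tree.leaf_labels])
    anc_alignment = Alignment(list(tree.ancestor_labels),
                              [to_row(lbl) for lbl in tree.ancestor_labels])

    events: List[IndelEvent] = []
    for branch, kind, ids in raw_events:
        cols = sorted(col_index[c] for c in ids if c in col_index)
        if not cols:
            continue            # event fell entirely in stripped columns
        # split runs that stripping made non-contiguous
        run = [cols[0]]
        for c in cols[1:]:
            if c == run[-1] + 1:
                run.append(c)
            else:
                events.append(IndelEvent(branch, kind, run[0], run[-1]))
                run = [c]
        events.append(IndelEvent(branch, kind, run[0], run[-1]))

    subs_final: Dict[str, List[Tuple[int, str, str]]] = {}
    for branch, subs in substitutions.items():
        subs_final[branch] = [
            (col_index[c], x, y) for c, x, y in subs if c in col_index
        ]
    return SimulationResult(tree, alignment, anc_alignment, sorted(
        events, key=lambda e: (e.branch, e.start)
    ), subs_final, config)


def replay_events(result: SimulationResult) -> Dict[str, str]:
    """Re-derive every node's aligned row from the root row plus the
    recorded per-branch events and substitutions (bookkeeping check)."""
    tree = result.tree
    gap = result.alignment.gap_char
    n = result.alignment.n_cols
    by_branch: Dict[str, List[IndelEvent]] = {}
    for ev in result.events:
        by_branch.setdefault(ev.branch, []).append(ev)
    rows: Dict[str, List[str]] = {
        tree.root.label: list(result.row(tree.root.label))
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        row = list(rows[node.parent.label])
        for col, x, y in result.substitutions.get(node.label, []):
            row[col - 1] = y
        for ev in by_branch.get(node.label, []):
            if ev.kind == "deletion":
                for c in range(ev.start, ev.end + 1):
                    row[c - 1] = gap
            else:
                true_row = result.row(node.label)
                for c in range(ev.start, ev.end + 1):
                    row[c - 1] = true_row[c - 1]
        rows[node.label] = row
    return {lbl: "".join(r) for lbl, r in rows.items()}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def true_branch_events(result: SimulationResult) -> Set[Tuple[str, int, int]]:
    """The truth event set in the matching currency: per-branch events
    derived from the true alignments' position sets."""
    out: Set[Tuple[str, int, int]] = set()
    tree = result.tree
    for node in tree.preorder():
        if node.parent is None:
            continue
        evs = extract_indel_events(
            result.positions(node.parent.label),
            result.positions(node.label),
            node.label,
        )
        out.update(ev.key() for ev in evs)
    return out


def inferred_branch_events(
    result: SimulationResult,
    position_sets: Dict[str, Sequence[int]],
) -> Set[Tuple[str, int, int]]:
    """Per-branch events implied by inferred ancestor position sets
    (extant positions come from the true alignment)."""
    out: Set[Tuple[str, int, int]] = set()
    tree = result.tree
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_pos = position_sets[node.parent.label]
        child_pos = (position_sets[node.label]
                     if node.label in position_sets
                     else result.positions(node.label))
        evs = extract_indel_events(list(parent_pos), list(child_pos), node.label)
        out.update(ev.key() for ev in evs)
    return out


def benchmark_method(
    result: SimulationResult,
    option: str,
    alignment: Optional[Alignment] = None,
    with_no_edge: bool = False,
) -> Tuple[Set[Tuple[str, int, int]], int]:
    """Run one indel option end to end on a simulation and collect its
    implied event set and root sequence length.

    Each ancestor's position set is taken from its *preferred path* (the
    single nominated sequence), matching an evaluation based on the
    emitted ancestral alignments rather than on full POGs.  ``alignment``
    overrides the truth's extant alignment (e.g. a perturbed one).
    """
    from .paths import edge_weights, preferred_path
    from .pog import build_extant_pog
    from .indel import infer_indels

    aln = alignment if alignment is not None else result.alignment
    pogs = infer_indels(aln, result.tree, option, with_no_edge)
    extant_pogs = {sid: build_extant_pog(aln, sid) for sid in aln.ids}
    positions: Dict[str, List[int]] = {}
    root_len = 0
    for k, pog in pogs.items():
        w = edge_weights(result.tree, extant_pogs, k)
        path = preferred_path(pog, w)
        positions[k] = path.positions
        if k == result.tree.root.label:
            root_len = len(path)
    return inferred_branch_events(result, positions), root_len


@dataclass
class EvaluationReport:
    """Recovery accuracy and cross-method overlap statistics."""

    accuracy: Dict[str, float]                       # method -> % recovered
    n_true_events: int
    consistently_identified: int
    consistently_missed: int
    unique_events: Dict[str, List[Tuple[str, int, int]]]
    root_length_match: Dict[str, bool]


def evaluate_recovery(
    truth: SimulationResult,
    inferred: Dict[str, Set[Tuple[str, int, int]]],
    root_lengths: Optional[Dict[str, int]] = None,
) -> EvaluationReport:
    """Score each method's inferred event set against the truth.

    Events match exactly on (branch, start, end); accuracy is the
    percentage of true events recovered.  Also reported: events found by
    every method, events missed by every method, and per-method unique
    recoveries.
    """
    true_set = true_branch_events(truth)
    n_true = len(true_set)
    accuracy: Dict[str, float] = {}
    hits: Dict[str, Set] = {}
    for method, events in inferred.items():
        h = true_set & events
        hits[method] = h
        accuracy[method] = 100.0 * len(h) / n_true if n_true else 100.0
    if hits:
        all_hit = set.intersection(*hits.values())
        any_hit = set.union(*hits.values())
    else:
        all_hit, any_hit = set(), set()
    unique: Dict[str, List] = {}
    for method, h in hits.items():
        if len(hits) == 1:
            unique[method] = []      # uniqueness is a cross-method notion
            continue
        others = set().union(*(v for m, v in hits.items() if m != method))
        unique[method] = sorted(h - others)
    true_root_len = len(truth.positions(truth.tree.root.label))
    root_match = {}
    if root_lengths:
        root_match = {m: (l == true_root_len) for m, l in root_lengths.items()}
    return EvaluationReport(
        accuracy=accuracy,
        n_true_events=n_true,
        consistently_identified=len(all_hit),
        consistently_missed=len(true_set - any_hit),
        unique_events=unique,
        root_length_match=root_match,
    )


def fractional_distance(seq_a: str, seq_b: str, gap_char: str = "-") -> float:
    """D/L: substitutions over mutually non-gapped homologous positions."""
    if len(seq_a) != len(seq_b):
        raise InvalidParameterError("aligned rows must have equal length")
    L = 0
    D = 0
    for x, y in zip(seq_a, seq_b):
        if x != gap_char and y != gap_char:
            L += 1
            if x != y:
                D += 1
    if L == 0:
        raise PogasrError("no mutually non-gapped positions; distance undefined")
    return D / L


def perturb_alignment(
    result: SimulationResult,
    rng: np.random.Generator,
    max_shift: int = 2,
) -> Alignment:
    """Locally shift gap-run boundaries to emulate realignment noise.

    Each row's residues keep their order and identity; only the gap
    placement moves, each gap run's boundary shifting by up to
    ``max_shift`` columns where room permits.  With ``max_shift=0`` the
    alignment is returned unchanged.
    """
    gap = result.alignment.gap_char
    new_rows: List[str] = []
    for row in result.alignment.rows:
        cells = list(row)
        if max_shift > 0:
            runs = _gap_runs_idx(cells, gap)
            for start, end in runs:
                shift = int(rng.integers(-max_shift, max_shift + 1))
                cells = _shift_run(cells, start, end, shift, gap)
        new_rows.append("".join(cells))
    return Alignment(list(result.alignment.ids), new_rows)


def _gap_runs_idx(cells: List[str], gap: str) -> List[Tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(cells):
        if c == gap and start is None:
            start = i
        elif c != gap and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(cells) - 1))
    return runs


def _shift_run(cells: List[str], start: int, end: int, shift: int,
               gap: str) -> List[str]:
    """Slide a gap run by swapping it with flanking residues where possible."""
    if shift == 0:
        return cells
    step = 1 if shift > 0 else -1
    for _ in range(abs(shift)):
        if step > 0:
            if end + 1 >= len(cells) or cells[end + 1] == gap:
                break
            cells[start], cells[end + 1] = cells[end + 1], cells[start]
            start += 1
            end += 1
        else:
            if start - 1 < 0 or cells[start - 1] == gap:
                break
            cells[end], cells[start - 1] = cells[start - 1], cells[end]
            start -= 1
            end -= 1
    return cells
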