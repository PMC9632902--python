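"""Partial-order graphs over alignment columns.

Three POG kinds share one coordinate system: extant POGs (one chain per
aligned sequence), the input POG (the entrywise sum of all extant POG
adjacency matrices) and ancestor POGs (inferred; forward edge support is
stored strictly above the diagonal of the support matrix and backward
support strictly below it).

Nodes are the extended index set ``0..N+1``: virtual start node 0,
alignment columns ``1..N``, virtual end node ``N+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core_model import Alignment, InvalidParameterError, PogasrError


class DisconnectedPOGError(PogasrError):
    """No complete 0 -> N+1 path exists."""


@dataclass
class ExtantPOG:
    """The single chain of character nodes for one extant sequence."""

    seq_id: str
    n_cols: int
    positions: List[int]           # I(j): 1-based columns with content
    characters: Dict[int, str]     # column -> amino acid

    @property
    def edges(self) -> List[Tuple[int, int]]:
        chain = [0] + self.positions + [self.n_cols + 1]
        return list(zip(chain[:-1], chain[1:]))

    def edge_set(self) -> Set[Tuple[int, int]]:
        return set(self.edges)

    def to_matrix(self) -> np.ndarray:
        E = np.zeros((self.n_cols + 2, self.n_cols + 2), dtype=int)
        for a, b in self.edges:
            E[a, b] = 1
        return E

    def to_aligned_row(self, gap_char: str = "-") -> str:
        out = [gap_char] * self.n_cols
        for i in self.positions:
            out[i - 1] = self.characters[i]
        return "".join(out)


@dataclass
class InputPOG:
    """Joint edge counts over all extant sequences (E*)."""

    n_cols: int
    counts: np.ndarray             # (N+2, N+2), above-diagonal only

    def next_nodes(self, a: int) -> List[int]:
        return neighbors(self.counts, a, "forward")

    def prev_nodes(self, b: int) -> List[int]:
        return neighbors(self.counts, b, "backward")


@dataclass
class AncestorPOG:
    """An inferred ancestor POG with directional edge support.

    ``support[a, b]`` (a < b) is 1 when edge (a, b) was optimal in the
    forward inference; ``support[b, a]`` is 1 when it was optimal
    backward.  An edge is in the POG iff the two entries sum to > 0, and
    is *bi-directional* (preferred) iff they sum to 2.
    """

    label: str
    n_cols: int
    support: np.ndarray            # (N+2, N+2) in {0, 1}
    states: Dict[int, str] = field(default_factory=dict)
    distributions: Dict[int, np.ndarray] = field(default_factory=dict)

    def edge_support_sum(self, a: int, b: int) -> int:
        if not a < b:
            raise InvalidParameterError("edge must satisfy a < b")
        return int(self.support[a, b] + self.support[b, a])

    def has_edge(self, a: int, b: int) -> bool:
        return self.edge_support_sum(a, b) > 0

    def is_bidirectional(self, a: int, b: int) -> bool:
        return self.edge_support_sum(a, b) == 2

    def edges(self) -> List[Tuple[int, int]]:
        fwd = set(zip(*np.nonzero(np.triu(self.support, 1))))
        bwd = set((a, b) for b, a in zip(*np.nonzero(np.tril(self.support, -1))))
        return sorted(fwd | bwd)

    def combined_matrix(self) -> np.ndarray:
        """Above-diagonal presence matrix (support sum > 0)."""
        upper = np.triu(self.support, 1)
        lower = np.tril(self.support, -1).T
        return ((upper + lower) > 0).astype(int)

    def positions(self) -> List[int]:
        """I(k): nodes on at least one complete path."""
        return reachable_positions(self.combined_matrix())

    def prune_to_paths(self) -> List[int]:
        """Drop support touching nodes off every complete path.

        Returns the columns that were dropped.  Inference can leave
        locally optimal edges whose nodes cannot form a valid sequence;
        mapping the encoding to a valid POG requires removing them.
        """
        keep = set(self.positions()) | {0, self.n_cols + 1}
        dropped = sorted(
            set(np.nonzero(self.support.sum(axis=0) + self.support.sum(axis=1))[0])
            - keep
        )
        for i in dropped:
            self.support[i, :] = 0
            self.support[:, i] = 0
        return [int(i) for i in dropped]


# ---------------------------------------------------------------------------
# Construction and queries
# ---------------------------------------------------------------------------

def build_extant_pog(alignment: Alignment, j) -> ExtantPOG:
    """The chain POG through the non-gap columns of row ``j``.

    A fully gapped row yields the single edge (0, N+1) so that the input
    POG remains well defined and indel inference can treat the sequence
    as all-deleted.
    """
    if isinstance(j, str):
        seq_id = j
    else:
        seq_id = alignment.ids[j]
    row = alignment.row(seq_id)
    positions = alignment.content_columns(seq_id)
    characters = {i: row[i - 1] for i in positions}
    return ExtantPOG(seq_id, alignment.n_cols, positions, characters)


def build_input_pog(alignment: Alignment) -> InputPOG:
    """E* — the entrywise sum of all extant POG adjacency matrices."""
    n = alignment.n_cols
    counts = np.zeros((n + 2, n + 2), dtype=int)
    for sid in alignment.ids:
        for a, b in build_extant_pog(alignment, sid).edges:
            counts[a, b] += 1
    return InputPOG(n, counts)


def neighbors(E: np.ndarray, node: int, direction: str) -> List[int]:
    """next(E, node) / prev(E, node) on any adjacency or count matrix."""
    n = E.shape[0]
    if not 0 <= node < n:
        raise IndexError(f"node {node} out of range 0..{n - 1}")
    if direction == "forward":
        return [int(b) for b in np.nonzero(E[node, :])[0] if b > node]
    if direction == "backward":
        return [int(a) for a in np.nonzero(E[:, node])[0] if a < node]
    raise InvalidParameterError(f"unknown direction {direction!r}")


def reachable_positions(E: np.ndarray, raise_on_disconnected: bool = False) -> List[int]:
    """path(E): columns reachable from 0 forward AND from N+1 backward.

    Returns the empty list when no complete path exists; with
    ``raise_on_disconnected`` a :class:`DisconnectedPOGError` is raised
    instead so callers can diagnose broken POGs.
    """
    n = E.shape[0]
    end = n - 1
    fwd = _closure(E, 0, "forward")
    bwd = _closure(E, end, "backward")
    if end not in fwd or 0 not in bwd:
        if raise_on_disconnected:
            raise DisconnectedPOGError("no complete 0 -> N+1 path")
        return []
    return sorted((fwd & bwd) - {0, end})


def _closure(E: np.ndarray, start: int, direction: str) -> Set[int]:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nxt in neighbors(E, node, direction):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def contains_sequence_path(pog: AncestorPOG, positions: Sequence[int]) -> bool:
    """Does the POG contain the complete path spelled by ``positions``?

    Used to test whether an ancestor POG accommodates a linear sequence
    prediction made by another tool.
    """
    positions = list(positions)
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise InvalidParameterError("positions must be strictly increasing")
    if any(not 1 <= p <= pog.n_cols for p in positions):
        raise InvalidParameterError("positions must lie in 1..N")
    chain = [0] + positions + [pog.n_cols + 1]
    return all(pog.has_edge(a, b) for a, b in zip(chain[:-1], chain[1:]))
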