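"""Shared model layer: alignments, rooted trees and substitution models.

Coordinate convention used throughout the package: alignment columns are
1-based (columns ``1..N``), with two virtual terminal nodes ``0`` and
``N+1`` bracketing every partial-order graph.  All public APIs use this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._model_data import AA_ORDER, EMPIRICAL_MODELS

AMINO_ACIDS: Tuple[str, ...] = tuple(AA_ORDER)

#: IUPAC ambiguity codes mapped to the sets of amino acids they stand for.
#: Ambiguous residues are treated as missing data restricted to the
#: compatible states.
AMBIGUITY_CODES: Dict[str, Tuple[str, ...]] = {
    "X": AMINO_ACIDS,
    "B": ("D", "N"),
    "Z": ("E", "Q"),
    "J": ("I", "L"),
}

GAP_CHARS = ("-", ".")


class PogasrError(Exception):
    """Base class for errors raised by this package."""


class InvalidParameterError(PogasrError, ValueError):
    pass


class UnsupportedModelError(PogasrError, ValueError):
    pass


class ConsistencyError(PogasrError, ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A multiple sequence alignment of amino-acid sequences.

    Rows are gapped strings of identical length ``N``; columns are indexed
    ``1..N``.  The gap character denotes absence of content.
    """

    ids: List[str]
    rows: List[str]
    gap_char: str = "-"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InvalidParameterError("ids and rows differ in length")
        if not self.rows:
            raise InvalidParameterError("alignment must contain >= 1 sequence")
        n = len(self.rows[0])
        if n < 1:
            raise InvalidParameterError("alignment must have >= 1 column")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise InvalidParameterError(
                    f"row {sid!r} has length {len(row)}, expected {n}"
                )
        if len(set(self.ids)) != len(self.ids):
            raise InvalidParameterError("sequence identifiers must be unique")
        allowed = set(AMINO_ACIDS) | set(AMBIGUITY_CODES) | {self.gap_char}
        for sid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - allowed
            if bad:
                raise InvalidParameterError(
                    f"row {sid!r} contains symbols outside the alphabet: {sorted(bad)}"
                )
        self.rows = [r.upper() for r in self.rows]
        self._index = {sid: j for j, sid in enumerate(self.ids)}

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def row(self, key) -> str:
        """Row by integer index or identifier."""
        if isinstance(key, str):
            key = self._index[key]
        return self.rows[key]

    def index_of(self, sid: str) -> int:
        return self._index[sid]

    def content_columns(self, key) -> List[int]:
        """1-based columns where the row has non-gap content (the set I(j))."""
        row = self.row(key)
        return [i + 1 for i, c in enumerate(row) if c != self.gap_char]

    def ungapped(self, key) -> str:
        return self.row(key).replace(self.gap_char, "")


# ---------------------------------------------------------------------------
# Rooted phylogenetic tree
# ---------------------------------------------------------------------------

class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class PhyloTree:
    """A rooted tree with branch lengths over the alignment's identifiers.

    Internal nodes without labels are assigned depth-first labels
    ``N0`` (root), ``N1``, ``N2``, ... in preorder, which makes the
    labelling deterministic for a given topology.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._label_ancestors()
        self.nodes: Dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.label in self.nodes:
                raise InvalidParameterError(f"duplicate node label {node.label!r}")
            if node.length < 0:
                raise InvalidParameterError(
                    f"negative branch length at {node.label!r}"
                )
            self.nodes[node.label] = node
        self.leaf_labels: List[str] = [n.label for n in self.preorder() if n.is_leaf]
        self.ancestor_labels: List[str] = [
            n.label for n in self.preorder() if not n.is_leaf
        ]

    # -- construction -------------------------------------------------------

    def _label_ancestors(self) -> None:
        counter = 0
        for node in self.preorder():
            if not node.is_leaf and not node.label:
                node.label = f"N{counter}"
                counter += 1
            elif not node.is_leaf:
                counter += 1

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a rooted Newick string (terminating ';' optional)."""
        root, rest = _parse_newick_node(newick.strip().rstrip(";"))
        if rest.strip():
            raise InvalidParameterError(f"trailing characters in Newick: {rest!r}")
        return cls(root)

    def to_newick(self, include_internal_labels: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_internal_labels and node.label:
                    s += node.label
            if node.parent is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    # -- queries ------------------------------------------------------------

    def parent_label(self, label: str) -> Optional[str]:
        """The parent map kappa; None at the root."""
        node = self.nodes[label]
        return node.parent.label if node.parent is not None else None

    def children_labels(self, label: str) -> List[str]:
        return [c.label for c in self.nodes[label].children]

    def subtree_leaves(self, label: str) -> List[str]:
        """Extant identifiers below (and including) the named node: J(k)."""
        node = self.nodes[label]
        out: List[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(reversed(n.children))
        return out

    def check_against_alignment(self, alignment: Alignment) -> None:
        tree_leaves = set(self.leaf_labels)
        aln_ids = set(alignment.ids)
        if tree_leaves != aln_ids:
            only_tree = sorted(tree_leaves - aln_ids)
            only_aln = sorted(aln_ids - tree_leaves)
            raise ConsistencyError(
                "tree leaves and alignment identifiers differ; "
                f"only in tree: {only_tree}; only in alignment: {only_aln}"
            )


def _parse_newick_node(s: str) -> Tuple[TreeNode, str]:
    """Recursive-descent Newick parser; returns (node, remaining string)."""
    s = s.lstrip()
    node = TreeNode()
    if s.startswith("("):
        s = s[1:]
        while True:
            child, s = _parse_newick_node(s)
            node.add_child(child)
            s = s.lstrip()
            if s.startswith(","):
                s = s[1:]
                continue
            if s.startswith(")"):
                s = s[1:]
                break
            raise InvalidParameterError(f"malformed Newick near {s[:30]!r}")
    # label (leaf name or internal label)
    i = 0
    while i < len(s) and s[i] not in ",():;":
        i += 1
    token = s[:i].strip()
    s = s[i:]
    if token:
        node.label = token
    if s.startswith(":"):
        s = s[1:]
        i = 0
        while i < len(s) and s[i] not in ",();":
            i += 1
        node.length = float(s[:i])
        s = s[i:]
    return node, s


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

class SubstitutionModel:
    """A time-reversible amino-acid substitution model.

    The instantaneous rate matrix Q is normalised so that one unit of
    branch length corresponds to one expected substitution
    (``-sum_a pi_a Q_aa = 1``), the convention used by PAML and most tree
    inference tools, which keeps branch lengths comparable across models.
    """

    def __init__(self, name: str, Q: np.ndarray, pi: np.ndarray,
                 alphabet: Sequence[str] = AMINO_ACIDS):
        self.name = name
        self.alphabet = tuple(alphabet)
        n = len(self.alphabet)
        Q = np.asarray(Q, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if Q.shape != (n, n) or pi.shape != (n,):
            raise InvalidParameterError("Q/pi shapes inconsistent with alphabet")
        if np.any(pi <= 0):
            raise InvalidParameterError("stationary frequencies must be positive")
        pi = pi / pi.sum()
        # renormalise to one expected substitution per unit time
        scale = -np.sum(pi * np.diag(Q))
        if scale <= 0:
            raise InvalidParameterError("rate matrix has non-positive total rate")
        self.Q = Q / scale
        self.pi = pi
        self._index = {a: i for i, a in enumerate(self.alphabet)}
        # Eigendecomposition of the symmetrised generator: for a reversible
        # Q, S = D^{1/2} Q D^{-1/2} is symmetric (D = diag(pi)), so
        # P(t) = D^{-1/2} V exp(L t) V' D^{1/2} with S = V L V'.
        sq = np.sqrt(self.pi)
        S = sq[:, None] * self.Q / sq[None, :]
        S = (S + S.T) / 2.0
        evals, evecs = np.linalg.eigh(S)
        self._evals = evals
        self._pre = evecs / sq[:, None]           # D^{-1/2} V
        self._post = evecs.T * sq[None, :]        # V' D^{1/2}

    @classmethod
    def from_exchangeabilities(cls, name: str, rates: Sequence[float],
                               freqs: Sequence[float]) -> "SubstitutionModel":
        """Build from a lower-triangle exchangeability vector (column-major
        over the canonical amino-acid order) and equilibrium frequencies."""
        n = 20
        R = np.zeros((n, n))
        idx = 0
        for col in range(n - 1):
            for row in range(col + 1, n):
                R[row, col] = R[col, row] = float(rates[idx])
                idx += 1
        if idx != len(rates):
            raise InvalidParameterError("expected 190 exchangeability values")
        pi = np.asarray(freqs, dtype=float)
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(name, Q, pi)

    def index(self, char: str) -> int:
        return self._index[char]

    def char_likelihood(self, char: str) -> np.ndarray:
        """Indicator vector over the alphabet; ambiguity codes spread a
        likelihood of 1 over their compatible states."""
        vec = np.zeros(len(self.alphabet))
        if char in self._index:
            vec[self._index[char]] = 1.0
        elif char in AMBIGUITY_CODES:
            for a in AMBIGUITY_CODES[char]:
                if a in self._index:
                    vec[self._index[a]] = 1.0
        else:
            raise InvalidParameterError(f"character {char!r} not in alphabet")
        return vec

    def transition_probabilities(self, distance: float, rate: float = 1.0) -> np.ndarray:
        """P(d) = exp(Q * distance * rate); rows sum to 1."""
        if distance < 0:
            raise InvalidParameterError("distance must be non-negative")
        if rate <= 0:
            raise InvalidParameterError("rate must be positive")
        if distance == 0:
            return np.eye(len(self.alphabet))
        t = distance * rate
        P = (self._pre * np.exp(self._evals * t)) @ self._post
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(model: SubstitutionModel, distance: float,
                             rate: float = 1.0) -> np.ndarray:
    """Functional alias for :meth:`SubstitutionModel.transition_probabilities`."""
    return model.transition_probabilities(distance, rate)


def load_model(name: str) -> SubstitutionModel:
    """Load a named empirical model (JTT, LG, WAG or Dayhoff)."""
    key = name.strip()
    lookup = {k.lower(): k for k in EMPIRICAL_MODELS}
    if key.lower() not in lookup:
        raise UnsupportedModelError(
            f"unknown model {name!r}; supported: {sorted(EMPIRICAL_MODELS)}"
        )
    canon = lookup[key.lower()]
    rates, freqs = EMPIRICAL_MODELS[canon]
    return SubstitutionModel.from_exchangeabilities(canon, rates, freqs)


# ---------------------------------------------------------------------------
# Per-column relative rates
# ---------------------------------------------------------------------------

@dataclass
class RateVector:
    """Per-column relative evolutionary rates; defaults to a uniform rate."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 1:
            raise InvalidParameterError("rates must be a vector")
        if np.any(self.rates <= 0):
            raise InvalidParameterError("rates must be strictly positive")

    @classmethod
    def uniform(cls, n_cols: int) -> "RateVector":
        return cls(np.ones(n_cols))

    def check_length(self, n_cols: int) -> None:
        if len(self.rates) != n_cols:
            raise InvalidParameterError(
                f"rate vector length {len(self.rates)} != alignment columns {n_cols}"
            )

    def __getitem__(self, column: int) -> float:
        """Rate at a 1-based alignment column."""
        return float(self.rates[column - 1])
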