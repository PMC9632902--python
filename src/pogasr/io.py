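"""Readers and writers for the standard formats the tool consumes and
emits: FASTA / Clustal alignments, Newick trees, per-column rate files,
POG JSON / DOT exports, marginal-distribution TSVs.

All coordinates in outputs are 1-based alignment columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from Bio import AlignIO, SeqIO

from .core_model import (
    Alignment,
    ConsistencyError,
    InvalidParameterError,
    PhyloTree,
    RateVector,
)
from .pog import AncestorPOG

PathLike = Union[str, Path]


class FormatError(InvalidParameterError):
    pass


def read_alignment(path: PathLike, format: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal alignment; '.' gaps are normalised to '-'."""
    if format not in ("fasta", "clustal"):
        raise FormatError(f"unsupported alignment format {format!r}")
    try:
        records = list(AlignIO.read(str(path), format))
    except ValueError as exc:
        # AlignIO rejects ragged FASTA; name the offender where we can
        if format == "fasta":
            seqs = list(SeqIO.parse(str(path), "fasta"))
            if seqs:
                n = len(seqs[0].seq)
                for rec in seqs:
                    if len(rec.seq) != n:
                        raise FormatError(
                            f"record {rec.id!r} has length {len(rec.seq)}, "
                            f"expected {n}"
                        ) from exc
        raise FormatError(str(exc)) from exc
    ids = [rec.id for rec in records]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate sequence identifiers: {dups}")
    rows = [str(rec.seq).replace(".", "-").upper() for rec in records]
    return Alignment(ids, rows)


def write_alignment(alignment: Alignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


def read_tree(path: PathLike, alignment: Optional[Alignment] = None) -> PhyloTree:
    """Read a rooted Newick tree; unlabelled ancestors get N0.. labels.

    A trifurcating (unrooted-style) root is rejected with instructions to
    root the tree; when an alignment is supplied, leaf identifiers are
    checked against it.
    """
    text = Path(path).read_text().strip()
    tree = PhyloTree.from_newick(text)
    if len(tree.root.children) > 2:
        raise InvalidParameterError(
            "tree root is trifurcating, suggesting an unrooted tree; "
            "root it (e.g. by midpoint or outgroup) before reconstruction"
        )
    if alignment is not None:
        tree.check_against_alignment(alignment)
    return tree


def write_tree(tree: PhyloTree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_rates(path: PathLike, n_cols: int) -> RateVector:
    """One relative rate per line (or 'column<TAB>rate'); missing columns
    default to 1."""
    rates = np.ones(n_cols)
    seen_pairs = False
    values: List[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) >= 2:
            seen_pairs = True
            col = int(parts[0])
            if not 1 <= col <= n_cols:
                raise FormatError(f"rate column {col} out of range 1..{n_cols}")
            rates[col - 1] = float(parts[1])
        else:
            values.append(float(parts[0]))
    if not seen_pairs and values:
        if len(values) != n_cols:
            raise FormatError(
                f"rate file has {len(values)} values, expected {n_cols}"
            )
        rates = np.asarray(values)
    return RateVector(rates)


# ---------------------------------------------------------------------------
# POG export / import
# ---------------------------------------------------------------------------

def pog_to_json(pog: AncestorPOG,
                weights: Optional[Dict[Tuple[int, int], float]] = None) -> dict:
    nodes = []
    for i in pog.positions():
        entry: dict = {"index": i}
        if i in pog.states:
            entry["state"] = pog.states[i]
        if i in pog.distributions:
            entry["distribution"] = [float(x) for x in pog.distributions[i]]
        nodes.append(entry)
    edges = []
    for a, b in pog.edges():
        edges.append({
            "from": int(a),
            "to": int(b),
            "forward": int(pog.support[a, b]),
            "backward": int(pog.support[b, a]),
            "weight": float(weights.get((a, b), 0.0)) if weights else None,
        })
    return {
        "ancestor": pog.label,
        "n_cols": pog.n_cols,
        "nodes": nodes,
        "edges": edges,
    }


def pog_from_json(data: dict) -> AncestorPOG:
    n = int(data["n_cols"])
    support = np.zeros((n + 2, n + 2), dtype=np.int8)
    for e in data["edges"]:
        a, b = int(e["from"]), int(e["to"])
        if e.get("forward"):
            support[a, b] = 1
        if e.get("backward"):
            support[b, a] = 1
    pog = AncestorPOG(data["ancestor"], n, support)
    for nd in data["nodes"]:
        if "state" in nd:
            pog.states[int(nd["index"])] = nd["state"]
        if "distribution" in nd:
            pog.distributions[int(nd["index"])] = np.asarray(nd["distribution"])
    return pog


def write_pog_json(pog: AncestorPOG, path: PathLike,
                   weights: Optional[Dict[Tuple[int, int], float]] = None) -> None:
    Path(path).write_text(json.dumps(pog_to_json(pog, weights), indent=1) + "\n")


def read_pog_json(path: PathLike) -> AncestorPOG:
    return pog_from_json(json.loads(Path(path).read_text()))


def pog_to_dot(pog: AncestorPOG) -> str:
    lines = ["digraph POG {", "  rankdir=LR;"]
    end = pog.n_cols + 1
    for i in [0] + pog.positions() + [end]:
        label = "start" if i == 0 else ("end" if i == end else
                                        f"{i}:{pog.states.get(i, '?')}")
        lines.append(f'  n{i} [label="{label}"];')
    for a, b in pog.edges():
        style = "solid" if pog.is_bidirectional(a, b) else "dashed"
        lines.append(f"  n{a} -> n{b} [style={style}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_marginal_tsv(dist, path: PathLike) -> None:
    """Rows = positions in I(k), columns = the 20 amino acids."""
    with open(path, "w") as fh:
        fh.write("# 1-based alignment columns\n")
        fh.write("column\t" + "\t".join(dist.alphabet) + "\n")
        for col in sorted(dist.distributions):
            probs = dist.distributions[col]
            fh.write(f"{col}\t" + "\t".join(f"{p:.6g}" for p in probs) + "\n")


def write_events_tsv(events, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tkind\tstart\tend\tlength\n")
        for ev in events:
            fh.write(f"{ev.branch}\t{ev.kind}\t{ev.start}\t{ev.end}\t"
                     f"{ev.length}\n")
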