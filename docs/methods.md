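# Methods

This note documents the models and procedures implemented in `pogasr`,
the design decisions taken where several readings were defensible, and
the limits of what the synthetic benchmark can show.

## Coordinates and data structures

Alignment columns are 1-based (`1..N`); every partial-order graph (POG)
is bracketed by virtual nodes `0` and `N+1`, and all public coordinates
use this convention. An extant POG is the chain through a sequence's
non-gap columns; a fully gapped row yields the single edge `(0, N+1)`
rather than an error, so the input POG E\* (the entrywise sum of extant
chains) stays well defined and indel inference treats the sequence as
all-deleted. Ancestor POGs store forward edge support strictly above
the diagonal of one square matrix and backward support strictly below
it; an edge is present when the two entries sum to > 0 and
bi-directional when they sum to 2.

## Substitution models

JTT, LG, WAG and Dayhoff are built from their published exchangeability
coefficients and equilibrium frequencies (embedded as constants), and
renormalised so one unit of branch length equals one expected
substitution per site — the PAML convention, chosen so branch lengths
are comparable across models. Transition matrices e^{Qd} are computed
by eigendecomposition of the symmetrised generator
D^{1/2} Q D^{-1/2} (D = diag(pi)), which is numerically stable for
reversible models; P(0) is the exact identity (no epsilon injection),
and zero-length branches are permitted. Ambiguity codes (X, B, Z, J)
enter likelihoods as indicator vectors over their compatible amino
acids, the standard missing-data treatment. Published model frequencies
are used (no +F re-estimation).

## Indel history inference

Three encodings, each resolvable by parsimony or joint ML, give the six
options BE-P (default), BE-ML, SIC-P, SIC-ML, PS-P, PS-ML.

**PS** treats each column as an independent binary content/gap
character. **SIC** identifies deletion events by their exact start and
end columns; a sequence is *present* for an event equal to one of its
own maximal gap runs, *inapplicable* (missing data) when the event is
strictly contained in one of its gap runs (longer on at least one
side — an equal run is "present"), and *absent* otherwise. **BE**
scores, per reference position, the choice among candidate right
neighbours (forward) and left neighbours (backward) drawn from E\*;
each edge is evaluated twice and is bi-directionally supported when
optimal both ways.

*Parsimony* is Sankoff with unit costs: keeping the child's state is
free, switching costs 1; extant chains force their own edges (an
absent edge carries a large finite sentinel cost of 1e9 rather than
IEEE infinity, keeping sums well defined — any assignment touching a
sentinel is infeasible). Ties are never broken during inference: a
state is recorded for an ancestor iff it occurs in at least one
globally optimal assignment (verified against exhaustive enumeration),
deferring resolution to path extraction. *ML* uses a uniform reversible
model with as many states as the encoding offers at that position
(n-state Jukes–Cantor-style, normalised to one expected change per unit
time), raw tree branch lengths, a uniform prior at the root, and exact
max-product inference; ties within 1e-9 in log-likelihood are retained
as sets.

**Missing data in BE.** By default (the "legacy" handling), an extant
lacking the reference position is free to take any state, and a
position entirely absent from an ancestor's own extant subtree is
excluded at that ancestor: its sequence skips the position, so traced
edges through excluded nodes are *contracted* into bridging edges
between retained nodes (dropping them outright can strand the traced
path and disconnect the POG — contraction guarantees a complete path).
With `--no-edge`, a distinguished "no edge" state instead competes
explicitly wherever some extant lacks the position, and exclusion is
decided by the inference itself.

**PS/SIC to POG.** Ancestor per-column states project to a POG by
chaining definitely-present columns; tied columns (both presence and
absence co-optimal) become optional nodes — edges run from any node to
each tied column before the next definite column and to that column
itself, so every subset of a tied run is a valid path. These edges are
recorded in both directions: bi-directionality is a BE-specific signal,
so PS/SIC alternatives are arbitrated purely by extant weights during
path extraction.

All ancestor POGs are pruned so every retained node lies on a complete
`0 -> N+1` path; dropped locally-optimal-but-path-inconsistent states
are logged by the pruning step's return value.

## Character inference

Each column is inferred on its position-specific tree: nodes (leaves
and ancestors) lacking content at the column are removed, an included
node attaches to its nearest included ancestor with branch lengths
summed additively through elided nodes, and nodes with no included
ancestor become tops of independent components. The prior at every
component top is the model's stationary distribution pi (standard for
reversible models). Joint inference is exact max-product with
traceback, ties broken lexicographically by alphabet order for
reproducibility; marginal inference is exact sum-product
(inside–outside) with per-node rescaling against underflow; both are
verified against brute-force enumeration over all ancestor-state
combinations. Per-column relative rates from an external estimator
multiply the branch lengths at that column; columns without a rate
default to 1.

**Variant ranking.** At a site of a marginal reconstruction, residues
are ranked by posterior mass; for each prefix set S the reported
truncation divergence D(q_S || p) — the relative entropy between the
posterior renormalised over S and the full posterior — equals −log of
the posterior mass captured by S, so the greedy posterior-sorted prefix
minimises it at every size. (The opposite divergence direction is
infinite for any proper subset, which is why this direction is the
operative one.) The site's Shannon entropy is reported alongside.

## Preferred-path extraction

Edge weights w_k(a,b) are the fraction of extants *in the subtree under
ancestor k* whose chain contains the edge. The preferred path minimises
the sum of gamma_k(a,b) = (1 + eta·(1−w))·(b−a) with eta = N for
non-terminal uni-directional edges and 1 otherwise; terminal edges
(from node 0 or into N+1) are exempt from the bi-directionality
penalty. Since gamma ≥ b−a, h(a) = N+1−a is an admissible, consistent
A\* heuristic and the search is exact; ties resolve to the
lexicographically smallest node sequence. Because the (b−a) factors sum
to N+1 along any complete path, sequences are scored evenly regardless
of edge count, and the total cost is bounded below by N+1 with equality
iff every edge is bi-directional (or terminal) with weight 1.

An alternative Markov-chain extractor maximises the sum of log weights
restricted to bi-directional out-edges wherever one exists (the
preference overrides weight); zero-weight admissible edges receive a
−1e9 log weight with a warning, and if the restriction dead-ends the
search is repeated over all edges.

## The simulator

`simulate_history` emulates an INDELible-style protocol: a root
sequence drawn from the model's stationary distribution evolves down a
rooted tree; substitutions per branch follow e^{Qd}; the number of
indel events on a branch is Poisson(indel_rate × branch length ×
current sequence length), split evenly between insertions and
deletions; lengths follow the truncated Zipfian law P(l) ∝ l^(−alpha).
Defaults are alpha 1.7, maximum length 10, the LG model, tree depth 1
(mean root-to-tip expected substitutions), insertion content from pi,
insertion slots uniform over len+1 positions and deletion starts
uniform over residues (truncated at the sequence end). Random trees
have a Yule (pure-birth) topology rescaled to the configured depth.
A global homology column space is maintained throughout, so true
alignments at every node are exact, each recorded event maps to a
branch and column range, and replaying the recorded events and
substitutions from the root reproduces every node's aligned row
exactly. Columns empty across all extants are stripped from extant and
ancestral alignments alike, with event coordinates remapped (events
that vanish entirely with stripped columns are dropped).

What the simulator does *not* emulate: alignment error (homology
columns are exact — `perturb_alignment` offers bounded random shifts of
gap-run boundaries as a controlled stand-in for realignment noise, a
synthetic emulation rather than a reproduction of an aligner),
rate heterogeneity across sites, domain-level structure, or biased
indel placement. Passing benchmarks here therefore shows correctness of
the inference machinery under the generative model, not performance on
real, misaligned families.

## Evaluation

Indel events are compared as (branch, start, end) triples with exact
coordinate matching, no partial credit. Both the truth's and each
method's event sets are derived the same way — from per-node position
sets via run extraction (maximal runs present in the parent and absent
in the child, uninterrupted by columns the child possesses; columns
absent from both, e.g. content private to other lineages, do not split
a run; at the root no events are emitted). Method position sets come
from each ancestor's *preferred path* — the emitted sequence — rather
than the full POG node set, since the POG legitimately retains
penalised alternative paths (e.g. through clade-specific insertions at
deeper ancestors) that are not part of the nominated ancestor.
Accuracy is the percentage of true events recovered; cross-method
reports count events uniformly identified, uniformly missed, and
unique to each method.

## Benchmark scale and a known knife-edge

The packaged benchmark runs at 100 taxa and root length 100 (rates
0.001 and 0.03, a few seeded replicates) so the whole suite completes
in well under a minute of compute; all inference engines are
additionally verified exactly against enumeration oracles at small
sizes, which is where correctness is actually established.

One behaviour deserves explicit documentation. An indel event that
falls on one of the two branches incident to the root is
*unpolarizable*: a deletion on the stem of one clade is
indistinguishable, at parsimony level, from an insertion on the sister
stem (both cost 1), so the root's presence state ties and the
preferred path resolves the tie by extant weight — i.e. toward the
majority clade, which is uncorrelated with the simulated truth. When a
simulation happens to place an indel on a root-stem branch subtending
more than half the extants, the parsimony options therefore recover a
root sequence whose length differs from the truth by that event's
length (the ML options usually resolve such ties correctly, because
branch lengths polarise the choice and longer stems both attract more
events and are favoured as the site of change). Root-length recovery
is consequently a per-replicate coin flip in the presence of
majority-side stem events rather than a guarantee; the benchmark
reports it as a match rate. No tie-breaking rule consistent with the
weight-based path objective can recover both stem insertions and stem
deletions, since they demand opposite resolutions of the same tie.

## Known limitations

- BE-ML's uniform model ignores that candidate-set sizes differ across
  positions sharing an edge; raw branch lengths are used throughout.
- SIC inherits simple indel coding's assumption of a linear gap
  superposition; partially overlapping deletions are inferred
  independently per event and conflicts surface only at POG assembly.
- The Markov-chain extractor's handling of zero weights (uniform
  fallback) is a pragmatic choice; the preferred-path A\* extractor is
  the default and the one verified against enumeration.
- Trees must be rooted; rooting is the caller's responsibility.
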