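# pogasr

Ancestral sequence reconstruction (ASR) for protein families, built on
partial-order graphs (POGs). Given a multiple sequence alignment and a
rooted phylogenetic tree with branch lengths, `pogasr` infers, for every
internal node of the tree, which alignment columns that ancestor
possessed (its indel history), the most probable amino acid at each of
those columns, and a single preferred ancestral sequence — while
retaining alternative, co-optimal indel histories as alternative paths
through each ancestor's POG. A seeded sequence-evolution simulator with
tracked indel events supports benchmarking of indel recovery.

It is aimed at molecular evolution researchers and protein engineers
who want ancestors (and ancestral *variants* — alternative residues and
insertion/deletion blocks) from large alignments.

## The model

**POGs over alignment columns.** Columns are indexed `1..N`, bracketed
by virtual start/end nodes `0` and `N+1`. Each extant sequence *j* is a
chain through its non-gap columns I(j); the *input POG* E\* sums all
extant chains; an *ancestor POG* E^(k) is inferred, with forward edge
support stored above the diagonal of its support matrix and backward
support below it. An edge is *bi-directional* (preferred) when it is
optimal in both directions.

**Indel histories.** Three encodings of the indel signal — per-column
presence (PS), simple indel coding by shared deletion start *and* end
(SIC, with present/absent/inapplicable states), and bi-directional edge
(BE) encoding, in which each position's candidate left and right
neighbours from E\* compete — are each resolved over the tree by maximum
parsimony or by joint maximum likelihood under a uniform
(Jukes–Cantor-style) model with as many states as candidates, giving six
options: `BE-P` (default), `BE-ML`, `SIC-P`, `SIC-ML`, `PS-P`, `PS-ML`.
For BE parsimony, keeping a child's edge is free and switching costs 1;
extant sequences force their own edges; co-optimal choices are retained.

**Character states.** Each column is inferred on its *position-specific
tree* (the input tree minus nodes without content at that column, branch
lengths summed through elided nodes) as a Bayesian network whose
conditional probabilities are e^{Qd} for an empirical model Q (JTT, LG,
WAG or Dayhoff, normalised to one expected substitution per unit time).
Joint reconstruction finds the exact most probable assignment over all
ancestors (max-product with traceback); marginal reconstruction gives
the exact posterior distribution at one queried ancestor (sum-product).
External per-column relative rates are supported.

**Preferred sequence.** Edges are weighted by the fraction of extants
under the ancestor containing them, w_k(a,b), and the preferred path
minimises

    gamma_k(a,b) = (1 + eta_k(a,b) * (1 - w_k(a,b))) * (b - a)

with eta = N for non-terminal uni-directional edges and 1 otherwise, so
uni-directional edges are only used when unavoidable and every complete
sequence is scored evenly. The search is A\* with the admissible
heuristic h(a) = N+1−a.

## Worked example

```bash
printf '>s1\nMKV-ALE\n>s2\nMKVTALE\n>s3\nMKVTALE\n>s4\nMRVTALE\n' > family.fasta
printf '((s1:0.3,s2:0.2)N1:0.15,(s3:0.2,s4:0.35)N2:0.15)N0;\n' > family.nwk
pogasr reconstruct --aln family.fasta --nwk family.nwk --out recon --indel BE-P --model JTT
cat recon/ancestors.fasta
```

prints

```
>N0
MKVTALE
>N1
MKVTALE
>N2
MKVTALE
```

one preferred sequence per ancestor: the gap in s1 is inferred as a
deletion on s1's own branch (three of four extants, spanning both
clades, retain the T), and s4's private R does not displace K at any
ancestor. A marginal reconstruction at the root,

```bash
pogasr reconstruct --aln family.fasta --nwk family.nwk --out recon_m --mode marginal --node N0
```

writes `recon_m/marginal_N0.tsv` with one row per root position and one
posterior probability per amino acid (column 2 gives K ≈ 0.962,
R ≈ 0.036 under JTT — the strength of support for K over the s4
variant). Each run
also writes per-ancestor POG JSON (nodes, edges, directional support,
weights) and the annotated tree.

Other verbs: `pogasr simulate` (evolve sequences with tracked indel
events down a random or supplied tree), `pogasr evaluate` (score indel
recovery of each inference option against a simulation's truth),
`pogasr variants` (rank alternative residues at a site of a marginal
reconstruction by posterior mass and truncation divergence).

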