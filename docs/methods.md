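# Methods

This note documents the model, the defaults, the numerical choices and the
known limitations of `gmalign`. The README gives the formulas; here we
explain why things are the way they are.

## Problem model and assumptions

Both inputs are simple undirected graphs over opaque protein identifiers.
Self-loops (homodimers) are dropped on input with a warning, duplicate and
reversed-duplicate edge lines are collapsed, and identifier comparison is
exact and case-sensitive. The first network must be the smaller one
(`|V1| ≤ |V2|`); the pipeline swaps file inputs automatically. The alignment
is a one-to-one partial map that the refinement stage completes to a total
map on `V1`.

The objective — sequence-weighted conserved edges — treats topology as
primary and sequence evidence as a multiplicative modulation per matched
endpoint pair. When no sequence table is supplied (or `α = 0`), all sequence
factors are 1 and the objective is the plain conserved-edge count.

## Similarity scores

**Local score `S_l` (k-neighbourhoods).** `N_k(v)` is everything within k
hops of `v` (excluding `v`); the profile records the induced subgraph's node
and edge counts and the members' degree sequence. Degrees in the degree
sequence — including the center's — are taken **within the induced
subgraph**. This choice is load-bearing: it makes `D(u,u) = |E(g_u^k)|`
exactly, so `S_l = 1` on isomorphic neighbourhoods with corresponding
centers, and it bounds each sorted-min sum by either subgraph's edge count,
so `S_l ≤ 1` always. (With full-graph member degrees both properties fail —
a star whose leaves have high outside degree already exceeds 1.) For `k ≥ 1`
the center's subgraph degree equals its full-graph degree, so the choice
only matters for neighbourhood members and for the degenerate `k = 0`, where
every pair scores 1 (an empty neighbourhood carries no evidence either way).
A `degree_scope="full"` option is retained for sensitivity analysis. The
maximum-common-subgraph lower bound on `S_l` holds for the *centered* MCS
(the common subgraph must map center to center); the test oracle enumerates
it by brute force on neighbourhoods of at most 6 nodes.

**Spectral score `S_g`.** Full dense symmetric eigendecomposition of the
Laplacian up to a configurable cap (default 3000 nodes); above it, an
iterative Lanczos solver retains the top `c ≤ 500` eigenpairs and the result
is flagged approximate. Eigenvector sign ambiguity is resolved by taking
absolute values. Within (near-)degenerate eigenspaces the eigenvector basis
is solver-dependent, so `S_g` is only basis-stable for simple spectra; for
reproducibility columns are ordered by eigenvalue (ties within 1e−9 broken
lexicographically by the absolute component vector). Entries are clipped to
[0, 1] against floating-point overshoot.

**Degree score `S_d`.** The 0/0 case (both nodes isolated) is defined as 1 —
isolated↔isolated is a perfect trivial match — and exactly one isolated
endpoint scores 0.

**Sequence score `S_seq`.** Raw scores are BLAST bit-scores or
−log10(e-value), with e-values ≤ 1e−180 clamped (so the raw score caps at
180) and e-values ≥ 1 mapped to 0; duplicated pairs keep their best score.
Normalisation divides by the global maximum over retained pairs. An empty
table forces `α = 0` with a logged warning rather than silently zeroing the
whole similarity.

## Defaults

| parameter | default | meaning |
|---|---|---|
| α | 0.0 | sequence weight in `S`; 0 = topology only |
| θ | 0.5 | degree-vs-neighbourhood balance inside `S_str` |
| k | 2 | neighbourhood hop radius |
| τ | 0.5 | anchor similarity threshold |
| δ | derived | `max(2|E1|/|V1|, 2|E2|/|V2|)` |
| X (patience) | 5 | consecutive non-improving refinement attempts |

θ = 0.5, k = 2 and X = 5 are the standard operating point for this family of
aligners; τ ≥ 0.5 keeps anchors high-confidence. An optional quantile rule
(`tau_quantile`) sets τ from the score distribution over degree-qualified
pairs; it is a pragmatic alternative, not a tuned equivalent of any
published auto-tuning procedure.

## Construction details

Anchor selection scans pairs in non-increasing `S` with ties broken
lexicographically by `(u, v)`; the scan stops at the first score below τ.
When no pair qualifies, the default fallback seeds the expansion with the
single best pair, since an aligner that returns nothing is rarely useful;
strict mode returns an empty matching instead. The expansion queue admits duplicate entries and checks
staleness at pop time; zero-score pairs are enqueued by default
(completeness over speed) with a flag to skip them on large inputs. Nodes
unreachable from any anchor are left for the refinement stage.

## Refinement details

Minimal-cover construction inserts shuffled nodes that still cover an
uncovered edge, then prunes (random order, to fixpoint) any cover node all
of whose neighbours are covered. Note a star graph has two minimal covers —
the hub, or all leaves — and the procedure can legitimately return either;
minimality, not minimum size, is what the refinement needs, since more
distinct minimal covers means more chances to free a badly matched node.

The acceptance comparator is the matching score with strict improvement
required; with `α = 0` or no sequence data this is the conserved-edge count.
The refinement weights are the pure integer matched-edge counts — no
similarity term is mixed in, so refinement optimises exactly the conserved-
edge structure the weights count. Rectangular assignments are handled by the solver directly (every
refinable `V1` node is assigned; zero-weight pairs allowed). Among equal-
weight optima the assignment is biased toward lexicographically earlier
(row, column) pairs by a perturbation strictly smaller than the integer
weight gaps, making the whole pipeline deterministic under a fixed seed.
Patience counts *consecutive* failures; any accepted improvement resets it.
A final completion pass pairs leftover `V1` nodes with leftover `V2` nodes
in identifier order.

One seeded generator stream drives everything random in a run (cover draws
and the per-iteration side choice); the synthetic generator likewise derives
all of its randomness from its own single seed.

## Synthetic benchmark generator

`generate_pair` emulates the situation real cross-species alignment
presents: a source network (Erdős–Rényi, duplication–divergence, or a
labelled caterpillar tree with distinct leg counts), a relabelled copy with
`⌊rewire_rate·|E1|⌋` edges removed and the same number of random non-edges
added, optional extra nodes attached by degree-preferential attachment, and
a sparse sequence-score table: each true pair receives a high bit-score-like
value (uniform 100–200) with probability `seq_signal` (default 0.9), and
`seq_noise_pairs` decoy pairs (default `n1`) receive low values (uniform
10–50). Rewiring preserves simplicity by rejection, so the ground-truth
mapping always conserves at least `1 − rewire_rate` of the edges.

What the generator does *not* emulate: the heavy-tailed degree
distributions, interaction noise heterogeneity and annotation biases of
real PPI data, nor actual sequences (scores only). Passing the synthetic
recovery tests therefore demonstrates correctness of the machinery and
robustness to moderate edge noise, not performance parity on BioGRID-scale
interactomes. The recorded benchmark table in `gmalign.datasets` carries
only published summary counts for capacity planning and consistency checks;
two of its eight rows (MM, DM) have printed average degrees inconsistent
with their own printed counts and are flagged as such rather than
"corrected".

The caterpillar family exists because isomorphism recovery is only
well-posed when degree profiles are distinguishable; on it the aligner must
(and does) reach EC = 1 from topology alone. Problem sizes in the tests and
the acceptance script (n₁ = 60–100, ten seeds for averaged statistics) keep
a full run in seconds while leaving every code path exercised.

## Biological measures

FC pools GO terms across BP/MF/CC by default (a per-category restriction is
available), and compares raw annotated term sets without ancestor
propagation. AFS uses Resnik term similarity — IC(t) = −ln p(t) with p(t)
the fraction of annotated corpus proteins carrying t or a descendant, corpus
= both networks' annotated proteins in the category — mixed per protein pair
by best-match average. The denominator divides by the number of annotated
`V1` proteins by default; a flag restores division by `|V1|`. Both
conventions appear in the literature and differ by a constant factor per
network pair; neither is claimed canonical here. Terms missing from the
ontology are skipped with a log message. Conserved pathway extraction maps
one pathway's protein set through the alignment and intersects validated
interaction sets; it makes no statistical claim, it reports counts.

## Known limitations

* The refinement is a local search: monotone in its objective, but with no
  optimality guarantee; badly seeded anchor expansions on highly symmetric
  graphs (e.g. isomorphic Erdős–Rényi pairs with many automorphism-like
  near-symmetries) can need several covers to untangle.
* `S_g` degrades gracefully but is theory-backed only for exact
  isomorphism; for very large networks the iterative approximation truncates
  the spectrum.
* Dense similarity matrices are O(|V1|·|V2|) memory; the expansion scorer is
  lazy, but stage 1's anchor scan is not.
* No statistical significance is attached to EC or to pathway counts.
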