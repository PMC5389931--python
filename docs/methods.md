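# Methods

This note documents the models implemented in `nudixclan`, their parameters
and defaults, the synthetic data used to exercise them, and the design
decisions taken where more than one reasonable choice existed.

## Evidence-confidence model (`nudixclan.evidence`)

Experimental support for a (protein, function) annotation is segregated into
two independent categories, genetic (phenotypes from knockout/knockdown in
the same species, or cross-species complementation) and biochemical (kinetic
constants, relative-activity screens, qualitative assays). Each record maps
to a score in [0, 1]; each category takes the maximum over its records; the
categories combine by a noisy-OR, S_overall = 1 − (1 − S_gen)(1 − S_bio),
reflecting the independence of physiological and in vitro measurements. A
missing category contributes 0, so S_overall degrades gracefully to the
present category's score.

Kinetic scores are anchored at round catalytic efficiencies:

| log10(kcat/Km) | 3 | 4 | 5 | 6 | 7 | zero activity |
|---|---|---|---|---|---|---|
| kcat/Km score | 0.10 | 0.20 | 0.50 | 0.85 | 0.99 | 0.01 |
| pseudo-kcat/Km score | 0.05 | 0.10 | 0.25 | 0.50 | 0.70 | 0.01 |

with linear interpolation in log10 between anchors. Outside the anchors the
scale is clamped: above 10^7 to the top score (confidence saturates), and for
nonzero values below 10^3 to the bottom anchor score, because only an exact
zero has a defined score below the bottom anchor; clamping keeps the scale
monotone and bounded without inventing anchors. A pseudo-kcat/Km for
substrate A is derived from a screen containing a reference substrate B with
known kcat/Km as (relA/relB)² × (kcat/Km)B — the square encoding the belief
that efficiency changes faster than screened activity — and scored on the
deliberately lower pseudo anchor row. Screens with no kinetic reference score
linearly from 0 (0%) to 0.1 (100%). Qualitative evidence (gel/HPLC for
common substrates 0.05, gel for rarely active substrates 0.5, X-ray with
bound substrate analog 0.5 for binding, 0.01 as activity evidence, bare
positive-activity reports 0.01) and genetic evidence (predicted phenotype
0.99, related 0.7, inexplicable 0.1, cross-species rescue 0.5) are fixed
lookups. Two of these constants are reported inconsistently in the source
literature of this scoring scheme (rescue 0.5 vs 0.7; the HPLC/X-ray pair);
we default to the consolidated assignment table and expose every constant in
a YAML-overridable `ScoreTable`.

The final adjustment computes, per protein, Z = (S_overall − mean)/SD over
all of that protein's annotations, then

    S_final = 1 − (1 − S_overall)/(1 + |Z|)  (Z > 0)
            = S_overall/(1 + |Z|)            (Z < 0)
            = S_overall                      (Z = 0).

SD is the population SD (divide by n) by default — stable for the small
per-protein annotation counts this model sees — with sample SD available by
configuration. SD = 0 (single annotation, or identical scores) defines all
Z = 0, the explicit pass-through case. The adjustment is monotone in rank:
it boosts above-mean annotations and damps below-mean ones, never reordering
them. One consequence worth stating: a protein assayed only against poor
substrates still has a relatively-best one, and that annotation's S_final is
boosted above its raw anchor score. This is the intended outlier behaviour,
not an artifact.

Records with relative activity above 100% (screens whose best substrate was
redefined midway) are clamped to 100 with a logged warning. Malformed rows
in an evidence TSV are logged with their row number and skipped.

## Tree partitioning (`nudixclan.partition`)

Patristic-distance clustering classifies a clade as a cluster when its mean
pairwise leaf distance falls below a percentile of the whole-tree distance
distribution. Computing that distribution exactly is O(n²) in both time and
memory, infeasible for trees with tens of thousands of leaves, so two exact
linear-time quantities stand in for it:

1. **Per-node means.** For node v with children c_i carrying leaf counts n_i
   and leaf-path sums S_i, the distances from c_i's leaves to v sum to
   A_i = S_i + n_i·len(edge_i), and the leaf pairs joined at v contribute
   Σ_{i<j}(n_j A_i + n_i A_j) distance over Σ_{i<j} n_i n_j pairs. One
   post-order pass yields every node's exact cross-pair mean. (The historical
   shortcut of assuming equal branch lengths under each node exists only to
   avoid the quadratic cost; the recurrence achieves the same cost exactly,
   so the approximation is not used.)
2. **Approximate whole-tree distribution.** Every leaf pair is represented
   once, at its most recent common ancestor, by that node's mean: the
   pair-count-weighted multiset {(mean_v, pairs_v)}. The percentile threshold
   (default p = 0.05) is the weighted percentile of this multiset, defined to
   agree exactly with numpy's linear-interpolation percentile of the expanded
   flat list; pair-count weighting (rather than one entry per node) is used
   so every pair carries equal weight.

Cluster selection is a pre-order descent that stops at the root-most nodes
with mean strictly below the threshold ("below" read strictly). Size bounds
(defaults min 400, max 4000, chosen for tractable downstream alignment at
production scale; tests scale them to min 4 / max 40) are then enforced:

* oversized clades are replaced by their root's children, recursively; a
  polytomy splits into all children at once;
* each undersized clade merges into its *adjacent* clade — the nearest other
  clade by patristic distance between representative nodes, preferring
  siblings, ties broken by smaller size then smallest leaf label — provided
  the result stays within the maximum; otherwise its leaves are pooled;
* all pooled and never-clustered leaves form one leftover group
  (`UNCLUSTERED_POOL`), mirroring downstream practice of aligning them as a
  single extra subgroup.

The output is deterministic for a fixed input tree: clades are emitted in
pre-order of their (first) representative node, leaves sorted within clades.
Zero-length branches are legal and contribute 0 to path sums. A tree smaller
than the minimum clade size goes entirely to the pool.

## Scaffold merging and motifs (`nudixclan.scaffold`)

Merging requires each subgroup alignment to contain every scaffold sequence
with (a) an identical ungapped sequence and (b) the scaffold rows' mutual
alignment preserved; both are verified and violations name the offending
sequence. Columns in which at least one scaffold row has a residue are
scaffold-homologous and merge across subgroups; maximal runs of columns in
which all scaffold rows are gapped are that subgroup's private insert blocks
and are emitted verbatim, padded with gaps in every other row. When several
subgroups insert at the same scaffold position, blocks appear in subgroup
input order (the merge is associative up to this documented ordering). The
output contains each scaffold row once, each added row once, and conserves
every row's ungapped sequence exactly — asserted in every test.

Motif scanning uses the canonical 23-position Nudix-box template
GX₅EX₇REUXEEXGU with X = any of the 20 standard residues and U a bulky
aliphatic (default {L, I, V}, configurable because usage of
"hydrophobic/bulky aliphatic" varies). Scanning operates on degapped
sequences; hits are reported in 1-based inclusive residue coordinates and
overlapping hits are all returned. The X-loop window defaults to starting 17
residues after the motif end with requested length 10 (the upper end of the
typical 5–10 range, since the true boundary is structure-specific), clamped
to bounds (2, 19) and truncated at the sequence end; fewer than 2 remaining
residues yields a no-window result distinct from an error.

## Function on phylogeny (`nudixclan.phylo`)

Midpoint rooting finds a diameter path by the two-sweep farthest-leaf method
(exact on trees with non-negative branch lengths) and reroots at its
midpoint, splitting an edge when needed. Ties between equally distant leaves
are broken toward the lexicographically smaller label at each sweep, making
the root deterministic; when several distinct diameter paths exist this may
select a different (equally valid) one than other conventions, but the
rooted tree always satisfies the defining property: the two deepest
root-to-leaf distances both equal half the diameter. An all-zero-length tree
has no midpoint and is an error.

A leaf is *characterized* when at least one of its functions reaches
`min_confidence` (default 0.2, the threshold below which annotations are
treated as unlikely to reflect physiological substrates; 0.5 is the stricter
"reliable" preset). A clade is functionally coherent for function f when it
has ≥ 2 characterized leaves and at least `coherence_fraction` of them carry
f (default 1.0 — strict agreement; the parameter is exposed because "most
characterized members" admits looser readings). Reported clades are maximal:
a qualifying clade nested in a larger qualifying clade is absorbed.
Domain-of-life composition is taken over the clade's annotated leaves with
viral leaves excluded from the count (viruses cut across cellular domains)
but flagged; `multi_domain` requires ≥ 2 cellular domains — the operational
criterion for a candidate ancestral function, not a biological conclusion.

`polyphyly_count` counts the maximal f-coherent clades, with single
characterized carriers counted as degenerate clades (a lone carrier
elsewhere in the tree is evidence against monophyly): 1 = monophyletic
carriers, ≥ 2 = homoplasy or repeated loss.

## Synthetic data (`nudixclan.simulate`)

The generators emulate the statistical structure the analyses assume, with
planted ground truth returned alongside:

* **Trees** — uniform random edge attachment (binary), i.i.d. exponential
  branch lengths with scale `branch_length_scale` (default 0.1 substitutions
  per site, a typical protein-domain scale), leaves labelled L0001… in
  pre-order; byte-identical output under a fixed seed.
* **Annotations** — each of `n_functions` (default 5) functions is planted
  on `origins_per_function` disjoint clades (default 1); every leaf of a
  planted clade carries the function with confidence uniform in
  (0.8, 0.99). Planting enforces separability: no two same-function origins
  are siblings and the path between them passes ≥ 3 background leaves, so
  independent origins remain distinguishable in principle; if no such
  placement exists the generator raises rather than silently planting an
  unrecoverable configuration. Background leaves carry a shared background
  function with probability 0.9 (most lineages have *some* characterized
  relative; fully uncharacterized gaps are rarer) or stay uncharacterized.
  Domains of life are clade-correlated: each planted clade draws one domain
  from `domain_mix` (default bacteria 0.50, archaea 0.20, eukaryota 0.25,
  virus 0.05, roughly the composition of large prokaryote-dominated
  families) and its leaves follow it with probability 0.9.
* **Evidence** — per protein, the true function receives a kcat/Km with
  log10 uniform in [6, 7] plus Gaussian noise of SD `evidence_noise`
  (default 0.5 log10 units, i.e. a ~3-fold typical measurement/assay
  spread); each of 3 candidate decoy substrates appears with probability
  `decoy_rate` (default 0.5) in the [3, 4] band with the same noise —
  a ≥ 100-fold true-vs-decoy separation, consistent with physiological
  substrates sitting orders of magnitude above non-substrates; 20% of
  proteins additionally receive a supporting knockout phenotype record.

One integer seed fans out via `numpy.random.SeedSequence.spawn` into
independent substreams per stage, so adding or re-running a later stage never
perturbs an earlier one.

What the generator deliberately does **not** model: sequence evolution (no
substitution process — trees and labels are simulated directly), correlated
assay biases across papers, annotation errors with systematic direction,
horizontal transfer, or unbalanced lineage sampling. Passing recovery tests
therefore demonstrates correctness of the inference machinery under clean,
well-separated conditions, not robustness to every pathology of curated
literature data.

## Test and acceptance problem sizes

The suite verifies exact values (anchor tables, the 0.948 worked
interpolation example, the 23-residue motif span, a hand-constructed
two-subgroup merge), oracle equivalence (per-node means vs an O(n²)
brute force on 200 random trees of ≤ 64 leaves at 1e-9; midpoint rooting vs
an all-pairs diameter oracle on 100 trees at 1e-9; weighted percentile vs
explicit multiset expansion), invariants (partition disjoint-cover/size
bounds on 200 random trees of 20–200 leaves with min 4 / max 40; percentile
monotonicity of coverage; rank preservation and range of the score
adjustment, via property-based testing), and planted-truth recovery
(polyphyly counts for 1 and 3 planted origins over 100 seeded replicates of
100-leaf trees, ≥ 95% required; true-function top ranking for 200 simulated
proteins at default noise, ≥ 95%). These sizes keep the full suite under a
minute while leaving the statistical checks well-powered.

## Known limitations

* The partitioner consumes a rooted tree as given; it does not build trees
  or re-root them (combine with `midpoint_root` when needed).
* `enforce_size_bounds` merges by representative-node distance; a merged
  clade's representative is the LCA of its parts, so later merges use the
  coarser position.
* The group summary table reports a within-group mean distance only for
  groups that coincide with a single tree clade.
* Motif scanning is pattern-based, not probabilistic: divergent Nudix boxes
  with substitutions in conserved positions (as in isomerases and
  glycosylases) are intentionally not matched by the canonical template;
  supply a custom pattern for those.
* X-loop boundaries are parameterized, not inferred; callers with structural
  knowledge should pass explicit offsets/lengths.
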