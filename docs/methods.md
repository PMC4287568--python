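# Methods

This note documents the models, conventions and numerical choices behind
`treealign`, in the spirit of the methods documentation of simulation
and statistics packages: what is computed, under which assumptions, and
where a design was genuinely open.

## Guide-tree combinatorics

A guide-tree is a strictly binary rooted tree whose leaves carry unique
sequence identifiers. Profile alignment is symmetric, so two trees that
differ only by swapping children at some nodes produce the same
alignment; all enumeration, deduplication and counting therefore work
*up to child swaps*.

* **Labeled trees.** `count_labeled_trees(n)` is the double factorial
  `(2n-3)!!`, computed in exact (arbitrary-precision) integer
  arithmetic because the count for 16 leaves (~6.19 × 10^15) overflows
  32-bit and approaches 64-bit limits in derived products.
  `enumerate_labeled_trees` materializes the count constructively by
  leaf insertion: the k-th label is attached above the root or on the
  edge above each of the `2k-4` non-root nodes of every tree on `k-1`
  labels, giving `(2n-3)!!` distinct trees with no deduplication step.
* **Canonical forms.** The labeled canonical form orders each node's
  children by the smallest leaf label they contain; the unlabeled form
  orders children by (leaf count, canonical string). Both are invariant
  under child swaps, and the unlabeled form is additionally invariant
  under relabeling. Canonical newick strings serve as dictionary keys
  for deduplication and profile caching.
* **Shapes and symmetry.** Unlabeled topologies are enumerated by the
  standard Wedderburn–Etherington recursion (combine shapes on `a` and
  `n-a` leaves; unordered pairs when `a = n-a`). The symmetry degree
  `s` counts internal nodes whose two child subtrees are isomorphic;
  the automorphism group of the shape has order `2^s`, hence `n!/2^s`
  distinct labelings. `random_labeling` writes a uniform permutation
  onto the shape's leaf slots; since each distinct labeling corresponds
  to exactly `2^s` permutations, the draw is uniform over distinct
  labelings (verified by chi-square in the test suite).
* **Shape order.** `shape_id` indexes shapes in lexicographic order of
  the canonical string. Analyses that need a balance order (the
  per-topology summaries) sort by Colless index with Sackin and then
  `shape_id` as tie-breakers; the indices genuinely disagree on
  intermediate shapes, so one primary index had to be fixed and
  declared.

## Balance indices

For a rooted binary tree, the report contains Sackin's index (sum of
leaf depths in edges), Colless' index (sum over internal nodes of the
absolute leaf-count difference of the two subtrees), the Shao–Sokal B1
"inverse maximum" index (sum over non-root internal nodes of the
reciprocal of the maximal edge count down to a leaf), and the Shannon
entropy in bits of the leaf-depth distribution. B1 and depth entropy
admit more than one published reading; the definitions above are the
ones implemented, chosen as the most common textbook forms over the
same quantity the other two indices summarize. Branch lengths are
always ignored by balance indices.

## Rooted Robinson–Foulds distance

The distance between two trees on the same label set is the size of the
symmetric difference of their sets of non-trivial clades (leaf sets of
internal nodes, excluding singletons and the full set). A rooted binary
tree on `n` leaves has `n-2` such clades, so the maximum distance is
`2(n-2)` — 12 for eight leaves, attained by any pair sharing no clade
(e.g. a caterpillar versus a balanced tree with interleaved labels).
Multifurcating trees and the unrooted bipartition-based RF are out of
scope.

## Midpoint rooting

Input trees are interpreted as unrooted (a degree-two root is
suppressed); every edge must carry a non-negative length. The root is
placed halfway along the longest leaf-to-leaf path, so the two maximal
root-to-leaf path lengths, one per root subtree, are equal. Ties for
the diameter are broken by the lexicographically smallest (sorted) pair
of end-leaf labels, making the operation independent of input traversal
order. If the midpoint falls exactly on a node, the root is attached
with a zero-length edge on the side of the path's far end.

## Sequence descriptors

* **k-tuple distance**: `1 - shared/(min(len) - k + 1)` with shared
  k-mers counted at the minimum of the two multiplicities. Default
  `k = 1`, the common choice for protein distance pre-computation; the
  denominator uses the shorter sequence so the distance stays in
  [0, 1].
* **Percent identity** is computed from an optimal global pairwise
  alignment under the *same* engine and parameters as the progressive
  aligner, as `100 × matches / columns where both sequences hold a
  residue`. Normalizing by residue-bearing columns (rather than
  alignment length) matches how identities of reference alignments are
  usually quoted.
* **Hydrophobic moment**: the Eisenberg consensus scale with the
  standard α-helical periodicity of 100°, `μH = |Σ H_i e^{iδ·i}|`
  summed over residues `i = 1..L`; `X` contributes zero. `hml` divides
  by length.
* **Isoelectric point**: Henderson–Hasselbalch net charge over the two
  termini and the D, E, C, Y, H, K, R side chains with the EMBOSS pKa
  table (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
  R 12.5, Y 10.1), solved by bisection on pH ∈ [0, 14] to 10⁻⁴. Net
  charge is strictly decreasing in pH, so the root is unique; for
  pathological compositions whose charge does not change sign inside
  the interval the nearer endpoint is returned.

The exact pKa/hydrophobicity tables and identity normalization used by
any given published utility differ between tools, so descriptor-based
orderings are reproducible within this package but not bit-identical to
other implementations.

## Guide-tree builders

Distance matrices come from k-tuple distances of unaligned sequences or
from `1 - identity/100` of pairwise alignments. Agglomerative trees use
`scipy.cluster.hierarchy.linkage`: single, complete, group average
(UPGMA), centroid (the "mean linkage" that merges clusters by centroid
distance — listed separately from UPGMA deliberately), and Ward's
minimum-variance criterion. Merge heights are half the merge distance,
so UPGMA reproduces an ultrametric input exactly, topology and heights;
branch lengths are height differences clamped at zero where centroid or
Ward linkage produces inversions. Neighbour joining (standard Q-matrix)
comes from scikit-bio; negative branch-length estimates are clamped to
zero and the unrooted result is midpoint rooted, the reasonable default
when no outgroup information exists.

Chained (pectinate) trees are populated so that the *first* id in the
requested order sits in the deepest cherry and is aligned first:
`(((id1,id2),id3),...,idn)`. This fixes the convention that, e.g.,
sorting by length ascending aligns short sequences before long ones.
Orderings are stable sorts on one primary and at most one secondary
descriptor key; remaining ties keep input order.

## The progressive aligner

The engine is a deliberately plain profile–profile aligner, because the
object of study is the first stage (the guide-tree), not the second:

* column score between two profile columns = sum of substitution scores
  over all residue pairs across the two profiles (gap characters
  contribute nothing), i.e. counts·BLOSUM62·counts;
* global affine-gap DP with three states; gap open 10 and extension 0.5
  per sequence pair, terminal gaps penalized like internal ones (a
  `free_end_gaps` flag is available); transitions between the two gap
  states are disallowed, so a gap column in one profile never abuts a
  gap column in the other — with the default penalties this sacrifices
  nothing, since a substitution score is never below `-(open+extend)`;
* no sequence weighting, no iterative refinement, no consistency
  transformation: iteration would change the alignment order and
  defeat the exploration.

Two properties the combinatorics rely on are enforced structurally.
*Symmetry*: operands are put in canonical order (the profile containing
the smallest sequence id first) before the DP, so swapping the children
of any guide-tree node cannot change the result — this is the premise
behind counting trees up to child swaps, and it is fuzz-tested.
*Determinism*: all DP arithmetic is exact 64-bit integer (scores are
scaled by `2·n1·n2`), and traceback ties have a fixed preference
(match, then gap in the second profile, then gap in the first), so
results are identical across platforms and run counts. An adapter to
external aligner binaries (FASTA + Newick in, aligned FASTA out) can be
layered on top of the same interfaces but is not part of the package.

## Scoring

TC is the fraction of *core* reference columns that appear intact as a
column of the test alignment; SP is the fraction of residue pairs from
core reference columns that share a column in the test. Residues are
matched by per-sequence ordinal (the k-th non-gap character), never by
character equality, so repeated residues cannot alias. The test
alignment may contain extra sequences (families padded with homologs);
only the reference sequences are scored, and SP normalizes by reference
pairs within core columns. Both scores are invariant to test row order
and to all-gap test columns, and SP ≥ TC always.

Core columns are taken from a supplied mask, or recomputed from
superposed C-alpha coordinates: a column is core iff it is gap-free in
every reference sequence and every pairwise C-alpha distance within the
column is at most 0.3 nm. No secondary-structure restriction is
applied, and no relaxed majority criterion is offered: partial-agreement
columns are not reliable anchors. A reference with zero core columns
raises a distinct error rather than returning 0, because real benchmark
masks can shrink drastically and silent zeros would corrupt averages.

## The simulator

`simulate_family` draws a root sequence from a fixed background
amino-acid composition and evolves it down a tree (random join order
with exponential branch lengths by default, or any supplied tree).
Along a branch of length `t`, each site substitutes with probability
`1 - exp(-rate·t)`, the replacement drawn from the background (so
observed divergence saturates at the background coincidence rate);
indel events are Poisson with rate `indel_rate·t·L`, equiprobably
insertions or deletions, geometric lengths (mean 1.8), uniform
positions. Column bookkeeping is exact: every residue carries a
persistent column id, insertions splice fresh ids into the global
column order, and the true alignment is read off at the leaves. Core
columns of a simulated reference are the gapless columns — the analogue
of full structural agreement.

Defaults (8 sequences, root length 150, substitution rate 1/site/unit,
indel rate 0.02, branch-length mean 0.25) produce families inside the
envelope of structure-derived benchmarks: 4–16 sequences, lengths tens
to hundreds, mean pairwise identities in the ~15–80% band (the defaults
land near 30%, a realistically hard family). `calibrate_identity`
bisects a branch-length scale factor (geometrically, since identity is
roughly log-linear in scale) until the mean identity over 100 replicate
seeds is within ±3 points of a target in [10, 95].

What the simulator does *not* emulate: substitution-rate matrices and
site-rate heterogeneity, domain architecture, compositional drift, and
real structural cores. Passing tests on simulated families therefore
validates the machinery — enumeration, alignment, scoring, strategy
plumbing — and qualitative behaviour, not benchmark-scale effect sizes;
no claim is made that simulated strategy rankings reproduce those
measured on curated structural benchmarks, which would require the
curated families and the external production aligners.

## Exploration

`exhaustive_exploration` scores one record per distinct labeled tree.
Profiles of small subtrees (up to 4 leaves) are cached under their
canonical newick, which removes most redundant work while keeping
memory bounded for the 135,135-tree eight-sequence case; runs are
resumable through a checkpoint TSV keyed by canonical newick, flushed
every 1,000 trees, so restarts cannot duplicate records. The loop is
serial and therefore trivially deterministic. `sample_exploration`
draws distinct labelings per shape uniformly without replacement
(capping at `n!/2^s` with a warning) for sequence counts where
exhaustion is impractical; an explicit shape list can restrict the
sample. Problem sizes used in the shipped tests — exhaustive runs at
4–6 sequences, ten 5-sequence families of root length 80 for the
end-to-end comparison — were chosen as the smallest sizes at which
every combinatorial and behavioural property under test is non-trivial.

`compare_strategies` builds one tree per named strategy per family
(clustering schemes on alignment-identity distances, NJ, the true tree,
chained trees by descriptor order or at random) and reports per-family
and mean TC/SP; a strategy failing on a family is recorded as missing
rather than aborting the comparison. For any family small enough to
explore exhaustively, every strategy's score is bounded by the
exhaustive optimum — a consequence of determinism and symmetry that the
test suite checks end-to-end.

## Known limitations

* The aligner is a clean baseline, not a reimplementation of any
  production aligner; absolute TC values are not comparable across
  engines.
* Balance-index definitions beyond Sackin and Colless vary in the
  literature; B1 and depth entropy here are one consistent reading.
* Exhaustive exploration beyond eight sequences is combinatorially out
  of reach by design; use sampling.
* The simulator's indel placement is uniform and memoryless; real
  indels cluster in loops.
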