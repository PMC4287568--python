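# treealign

Systematic exploration of guide-tree topology effects on progressive
multiple sequence alignment.

Progressive alignment builds a protein MSA by merging sequences and
intermediate profiles pairwise, in the order dictated by a rooted binary
*guide-tree*. Because early alignment decisions are frozen, the
guide-tree shapes the final alignment — but which trees are actually
good is an empirical question. For small families the question can be
answered exhaustively: on `N` sequences there are only

```
L_N = (2N-3)!!
```

distinct labeled guide-trees (trees are counted up to child swaps, since
profile alignment is symmetric), e.g. `L_4 = 15`, `L_5 = 105`,
`L_8 = 135,135`. The number of unlabeled topologies is the
Wedderburn–Etherington number (`U_8 = 23`, `U_16 = 10,905`), and a shape
whose symmetry degree is `s` (internal nodes with isomorphic child
subtrees) carries `N!/2^s` distinct labelings.

`treealign` is a library + CLI for researchers studying guide-tree
construction. It provides:

* **trees** — enumeration of all labeled guide-trees and unlabeled
  topologies, canonical forms, symmetry-aware counting, uniform random
  labelings of a shape;
* **tree_metrics** — balance indices (Sackin, Colless, Shao–Sokal B1,
  leaf-depth entropy), rooted Robinson–Foulds distance (clade symmetric
  difference; maximum `2(N-2)`), midpoint rooting, branch-length
  coefficient of variation;
* **descriptors** — k-tuple distance, pairwise percent identity,
  Eisenberg hydrophobic moment, Henderson–Hasselbalch isoelectric point,
  and the per-family `hi`/`lo` identity keys;
* **guide_builders** — UPGMA, single/complete/centroid (mean)/Ward
  linkage, neighbour joining (midpoint rooted), and perfectly chained
  trees populated by descriptor orderings (`len/a`, `hi/d`,
  `len/a+ip/d`, ...);
* **aligner** — a deterministic progressive profile–profile engine
  (BLOSUM62, affine gaps, sum-of-pairs column scores, no iteration or
  weighting) whose output is provably invariant under child swaps;
* **scoring** — TC (fraction of core reference columns reproduced
  intact) and SP (fraction of core residue pairs co-aligned) against a
  reference alignment, with core columns derived from superposed
  C-alpha coordinates at a 0.3 nm threshold when available;
* **synthetic_data** — a sequence-evolution simulator with exact
  true-alignment bookkeeping, emulating structure-derived benchmark
  families (4–16 sequences, lengths ~30–900, identities ~15–80%), plus
  identity calibration;
* **explore** — exhaustive or sampled scoring of every guide-tree,
  optimum identification, per-topology summaries ordered by imbalance,
  and named-strategy comparisons.

## Worked example

Simulate a mid-difficulty family of five sequences, score all 105
guide-trees, and compare standard strategies:

```python
import treealign as ta

config = ta.SimulationConfig(n_sequences=5, root_length=80,
                             branch_length_mean=0.4, indel_rate=0.05, seed=7)
family = ta.simulate_family(config)            # mean identity 37.2%

table = ta.exhaustive_exploration(family)      # 105 records
best_tc, best_trees, count = ta.find_best(table)
print(f"best TC {best_tc:.3f} attained by {count} of {len(table)} trees")
print("min RF from true tree to an optimum:",
      ta.min_rf_to(best_trees, family.true_tree))

print(ta.summarize_by_shape(table)[["shape_id", "colless", "n_trees",
                                    "tc_median", "tc_mean"]])
comp, _ = ta.compare_strategies([family], ["upgma", "nj", "single",
                                           "ward", "true_tree", "chained:hi/d"])
print(comp[["strategy", "mean_tc", "best"]])
```

prints

```
best TC 0.492 attained by 1 of 105 trees
min RF from true tree to an optimum: 6
 shape_id  colless  n_trees  tc_median  tc_mean
        0        2       30   0.303279 0.267213
        1        3       15   0.311475 0.271038
        2        6       60   0.311475 0.296448
    strategy  mean_tc  best
       upgma 0.360656  True
          nj 0.360656  True
      single 0.360656  True
        ward 0.360656  True
   true_tree 0.360656  True
chained:hi/d 0.229508 False
```

Reading the output: exactly one of the 105 guide-trees attains the best
TC score (0.492), and it sits at rooted-RF distance 6 from the true
evolutionary tree — the best alignment tree is not the phylogeny. The
per-shape summary orders the three 5-leaf topologies by increasing
Colless imbalance; the perfectly chained shape (Colless 6) has the best
mean over random labelings. Distance-based strategies all find the same
tree here, scoring 0.361 — far below the optimum, which is the
motivating gap for studying guide-tree construction.

The same workflow is available from the shell:

```bash
treealign simulate -n 5 -l 80 --seed 7 fam/
treealign run fam/ -o scores.tsv
treealign best scores.tsv
treealign summarize scores.tsv
treealign compare fam/ -s upgma -s chained:hi/d
```

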