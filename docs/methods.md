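# Methods

## Model and pipeline

The package analyses a fold-change gene expression matrix
`F = [F_ij]` (N genes × C doses-of-chemicals; mean log2 treated/control
ratio over m replicates).  When raw expression tensors are supplied, the
per-replicate fold change is `log2(E) − log2(E')` and replicates are
averaged; (chemical, dose, time) triples are flattened chemical-major
into columns labelled `<chemical>_<dose>_<time>` so the order is
recoverable.

The robust pipeline transforms `F` entrywise by the logistic function
`L(f) = 1/(1 + e^{−f})`, computed in the two-branch form
(`1/(1+e^{−f})` for `f ≥ 0`, `e^{f}/(1+e^{f})` otherwise) so that
arbitrarily large |f| saturates to 0 or 1 without overflow.  `L` is
strictly increasing, satisfies `L(−f) = 1 − L(f)`, and bounds every value
in (0, 1): a contaminated cell can displace any downstream mean or
distance by at most ~1.  The classical variant is identical with the
transform skipped; a single mode switch separates the two.

Rows and columns are clustered independently by Lance–Williams
agglomeration on Lp profile distances.  Both R `hclust` Ward variants are
provided with R semantics: `ward.d` applies the recurrence

    d(A∪B, C) = [(n_A+n_C) d(A,C) + (n_B+n_C) d(B,C) − n_C d(A,B)] / (n_A+n_B+n_C)

to the dissimilarities as given; `ward.d2` applies it to squared
dissimilarities and reports square-rooted heights (equivalent to scipy's
`ward` on Euclidean input).  The agglomerator is implemented in-package
because scipy lacks the unsquared `ward.D` variant; tests cross-check all
five linkages against scipy, against R's `hclust` via `Rscript`, and
against a from-scratch recursive re-computation of every inter-cluster
cost.  Minimal-cost ties (within 1e−12) merge the lexicographically
smallest (left id, right id) pair, making runs deterministic.  Cluster
counts are user choices (defaults `k_genes = 4`, `k_dcs = 3`, matching
the simulator's design); `suggest_k` offers the largest dendrogram height
gap as advice only, with ties resolved toward smaller k.

Each (gene cluster, DC cluster) pair is a co-cluster; its aLFCGE is the
arithmetic mean of its transformed cells, so the cell-weighted block
means conserve the global mean exactly.  Relabelling is greedy
diagonalisation: repeatedly assign the next diagonal index to the
largest-mean block whose row and column clusters are both unlabelled
(ties to smallest original ids); leftover clusters on the longer axis
follow in descending order of their best block.  The rule guarantees the
diagonal means are non-increasing and is idempotent.  Only the multiset
of block means and significance calls is considered meaningful; the
label strings themselves depend on this convention.

## Control chart

Significance of a block is a Shewhart-style decision on the transformed
scale with the blocks as subgroups: a block is upregulatory iff its mean
is strictly above `UCL = CL + k_σ · σ̂ / √n̄` and downregulatory below
LCL (`CL` = grand mean of all cells, `n̄` = mean block size,
`k_σ = 3` by default).  Three σ̂ estimators are available:

* `xbar_overall` (default): the overall sd of all transformed cells;
* `xbar_pooled`: the pooled within-block sd;
* `individuals`: `CL ± k·sd` of the flat sample, no subgroups (also the
  default for per-cell regulation calls on the fold-change scale, where
  the inclusive rule `F_ij ≥ UCL` / `≤ LCL` applies).

The default deserves a note.  Under the simulator's design the ±3 blocks
are nearly constant after the transform (cell sd ≈ 0.032) while the
noise-only blocks have cell sd ≈ 0.137, so the pooled within-block sd
(≈ 0.122) *under*-estimates the spread of an in-control block mean; with
3-sigma limits each null block then carries a 0.2–3% false-alarm
probability and about one dataset in twenty flags a spurious block.  The
overall sd (≈ 0.244) is inflated by the signal blocks, which here is a
feature: the limits (≈ 0.5 ± 0.06) still exclude the ±3 blocks by a wide
margin (their means sit at ≈ 0.053/0.947) while the familywise
false-alarm rate drops below 0.1%.  Per-cell calls and co-cluster calls
deliberately keep the quoted boundary conventions of their sources
(inclusive for cells, strict for blocks).

## Simulator and contamination models

`generate_fcge` draws `cell = block mean + N(0, σ²)` with σ² = 0.35 over
a 50 × 36 design: gene clusters of 10/10/10/20 and DC clusters built
from 12 chemicals × {Low, Middle, High} (chemicals 1–5 at Middle/High,
chemicals 6–10 at Middle/High, and all Low doses plus chemicals 11–12 as
the third, signal-free cluster).  Block means are +3 (GC1×DCC1,
GC2×DCC2), −3 (GC2×DCC1, GC3×DCC2) and 0 elsewhere.  All sizes, means
and the noise variance are configurable; a replicate-level mode
(`generate_replicate_stack`, m = 3) supports cell-level charts.  The
generator emits the mean-level matrix directly because that is the
matrix the method analyses.

Contamination replaces clean entries with `±N(10, 1)` draws (sign random
per cell), far outside the ±3 signal range:

* **THCM** (Tukey–Huber) is casewise: each gene row is independently
  replaced wholesale with probability ε (sweep default 0–40%);
* **ICM** is cellwise: each cell independently with probability ε
  (sweep default 0–0.025; at C = 36 the chance a row carries ≥ 1 outlier
  is `1 − 0.975^36 = 0.598`, the casewise-equivalent endpoint).

Masks and matrices are bitwise reproducible from the seed.

## Robustness diagnostics

The clustering error rate matches predicted to true clusters one-to-one
by maximum-overlap assignment (Hungarian algorithm on the contingency
table) and reports the percentage unmatched; this makes ER invariant to
relabelling and symmetric, and members of unmatchable clusters (when the
cluster counts differ) all count as errors.

The sensitivity curve probes one contaminated coordinate `y*` appended
to a gene profile against a reference coordinate of a second gene
(default: the mean of that gene's working-scale profile):

    SC_n(y*) = n [ T(y_1..y_{n−1}, y*) − T(y_1..y_{n−1}) ]

with T the 1-norm profile distance.  In robust mode everything including
`y*` is transformed first, so `|SC_n| ≤ n·max(ref, 1−ref)` exactly; in
classical mode SC grows linearly in `y*`.  The curve is reported in this
finite-sample form; its n → ∞ limit (the influence function) differs
only by the constant `−T(F)` offset.

`run_comparison_sweep` pairs every (seed, contamination) draw across all
distance-linkage combinations and both modes, clusters genes at the true
k, and tabulates mean ± sd ER.  It reports the gene-axis ER (the
quantity the method's row-entity comparison is about); column clustering
is exercised in the pipeline itself.

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script use the default 50 × 36
design with 30 independent seeds — enough for block-mean averages with
standard errors well below the 0.01 comparisons applied to them, while a
full run stays in the seconds range.  The linkage oracle suite uses 1000
random instances at n ≤ 8, where brute-force recomputation is exact.
Conservation and symmetry identities are asserted at 1e−9/1e−12;
degenerate inputs (constant data, k_σ = 0, m = 1 replicates, empty
networks) collapse to their analytically obvious outputs and are tested.

## Limitations

The simulator draws i.i.d. Gaussian noise within blocks; real FCGE
matrices carry correlated genes, batch structure and heavier tails, so
passing tests demonstrate correct mechanics and robustness in the planted
model, not performance guarantees on arbitrary real data.  Dendrogram
leaf ordering follows the merge sequence and is not claimed identical to
R's plotting order.  Bi-clustering comparators, ML-based cluster
stability scoring and pathway annotation of discovered biomarkers are out
of scope.
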