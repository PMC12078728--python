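# toxicoclust

Robust hierarchical co-clustering of fold-change gene expression (FCGE)
matrices for toxicogenomic biomarker discovery.

## The problem

A toxicogenomic screen measures gene expression in treated and control
animals across a panel of chemicals, dose levels and time points.  The
analysis matrix has genes in rows and *doses-of-chemicals* (DCs — one
chemical × dose × time condition) in columns, each cell holding the mean
log2 fold change over replicates.  Three questions matter: which genes are
differentially expressed (the toxicogenomic biomarkers), which groups of
DCs act through a shared mechanism, and — jointly — which *co-clusters*
(gene-cluster × DC-cluster blocks) are significantly up- or
down-regulatory.  Gene expression pipelines routinely leak outliers into
these matrices, and ordinary hierarchical co-clustering is fragile against
them.

## The method

1. **Logistic transform.** Every fold change `F_ij` is mapped to
   `x_ij = 1 / (1 + exp(-F_ij)) ∈ (0, 1)`, with `x = 0.5` at `F = 0`.
   Outliers can only saturate toward 0 or 1, so their leverage on
   distances is bounded — this single step is what makes the procedure
   robust.  Skipping it gives the classical variant.
2. **Two-way hierarchical clustering.** Genes and DCs are clustered
   separately (Euclidean / Manhattan / Minkowski distances; `ward.d`,
   `ward.d2` — both R `hclust` Ward variants — plus single / complete /
   average linkage) and cut into `k_genes` and `k_dcs` clusters.
3. **Co-cluster grid.** Each (gene cluster, DC cluster) block gets the
   mean of its transformed values (the *aLFCGE*); clusters are relabelled
   so the largest block means run down the principal diagonal.
4. **Control-chart significance.** An x̄-type Shewhart chart over the
   blocks calls a block significantly upregulatory when its aLFCGE is
   strictly above `UCL = CL + k·σ̂/√n̄` and downregulatory below the LCL.
5. **Networks.** The GC–DCC cluster network (one weighted edge per block)
   and the expanded gene–DC bipartite network, exportable as edge-list TSV
   or GraphML.

A block-model simulator (50 genes × 36 DCs, planted ±3 blocks, Gaussian
noise), Tukey–Huber casewise and independent cellwise contamination
models, the clustering error rate (optimal cluster matching) and Tukey
sensitivity curves make the robustness evaluation fully reproducible with
no external data.  Real FCGE matrices are consumed as TSV/CSV.

## Worked example

```sh
toxicoclust cocluster --simulate --seed 1 --out run1 --print-summary
```

runs the whole pipeline on one simulated matrix and prints the ranked
co-cluster table (also written to `run1/coclusters.tsv`):

```
 gene_cluster  dc_cluster      mean  n_cells  rank   significance
            1           1  0.948179      100     1             up
            2           2  0.938421      100     2             up
            3           1  0.511952      200     3  insignificant
            3           3  0.501553      320     4  insignificant
            2           3  0.498506      160     5  insignificant
            1           3  0.498342      160     6  insignificant
            4           3  0.497202      160     7  insignificant
            3           2  0.494118      200     8  insignificant
            2           1  0.485202      100     9  insignificant
            4           2  0.479149      100    10  insignificant
            4           1  0.053116      100    11           down
            1           2  0.050724      100    12           down
```

The two planted upregulatory blocks surface with aLFCGE ≈ 0.95 (well above
the chart's UCL ≈ 0.558), the two planted downregulatory blocks with
≈ 0.05, and the eight noise-only blocks sit near the 0.5 centre line —
twelve co-clusters, two up, two down.  `run1/` also contains the
transformed and reordered matrices, both linkage tables and cluster
assignments, the control-chart report, both networks and a run manifest.

The other subcommands: `toxicoclust simulate` (matrix + ground truth),
`evaluate` (error rate between two assignments), `sweep` (robust-vs-
classical error-rate sweep across contamination rates) and `network`
(re-export networks from a results bundle).

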