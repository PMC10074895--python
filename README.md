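# triadbias

Homoeolog expression-bias analysis for allopolyploid transcriptomes at bulk
and single-cell resolution.

In an allohexaploid (e.g. bread wheat, AABBDD), each *triad* of homoeologous
genes — one copy per subgenome — can contribute unequally to the
transcriptome. `triadbias` quantifies this asymmetry:

- **Simplex classification** (`triadbias.triad_core`): normalize each
  triad's (A, B, D) expression to sum to 1 and assign one of seven bias
  categories (`Balance`, `A/B/D.dominant`, `A/B/D.suppressed`) by Euclidean
  distance to ideal centroids on the 2-simplex. Triads below an expression
  floor are labelled `not_expressed`.
- **Pseudobulk pipeline** (`triadbias.bias_pipeline`): average single cells
  into per-cluster expression (counts-per-10k or raw mean), classify triads
  per cluster and in pooled/bulk data, break down bulk-balanced triads by
  their cluster-level categories, compute per-subgenome
  suppressed/dominant ratios, and summarize bias among marker genes.
- **Trajectory asymmetry** (`triadbias.trajectory_bias`): fraction of
  unbalanced triads along ordered pseudotime segments (explicit labels or
  equal-count bins) of a possibly branching trajectory.
- **Specificity & cross-species comparison** (`triadbias.specificity`):
  Shannon-entropy expression-specificity index `S = 1 − H/log2(n)`,
  per-cluster top specific genes, ortholog collapsing, Spearman
  cluster-by-cluster correlation with BH correction, and orthologous
  marker-overlap counts.
- **Synthetic data** (`triadbias.synthetic`): a generator for allopolyploid
  single-cell counts with planted per-cluster bias categories (Dirichlet
  compositions around centroids, negative-binomial totals, multinomial
  A/B/D split, Bernoulli dropout) and planted trajectory gradients — used
  as the test harness throughout.
- **I/O** (`triadbias.io`): 10x-style MTX/features/barcodes reader and
  byte-deterministic writer, annotation and dense-TSV readers.

## CLI

```sh
# generate a synthetic dataset
triadbias simulate --config sim.yaml --out simdir

# classify triads per cluster + bulk; writes bias_calls.tsv, summary.tsv,
# ratios.tsv, breakdown.tsv, ternary.csv
triadbias classify --matrix simdir/matrix --annotation simdir/annotation.tsv \
    --triads simdir/triads.tsv --min-total-expr 0.5 --norm cp10k --out outdir

# asymmetry along a trajectory (segment labels or equal-count bins)
triadbias trajectory --matrix simdir/matrix --annotation simdir/annotation.tsv \
    --triads simdir/triads.tsv --segments bins:4 --out trajectory_bias.tsv

# specificity scores and cross-species cluster correlation
triadbias specificity --matrix pseudobulk.tsv --out spec.tsv
triadbias crosscorr --m1 wheat.tsv --m2 rice.tsv --orthologs orth.tsv \
    --markers1 mk1.tsv --markers2 mk2.tsv --alpha 0.05 --out ccdir

# everything from one YAML config, with a reproducibility manifest
triadbias run-all --config run.yaml --seed 7 --out outdir
```

A `run-all` YAML either points at existing inputs (`matrix`, `annotation`,
`triads` paths) or contains a `simulate:` section with generator fields
(`n_triads`, `n_clusters`, `cells_per_cluster`, `category_probs`,
`dirichlet_concentration`, `dropout_rate`, `trajectory`, ...). Reruns with
the same seed reproduce every output byte-for-byte.

Triad tables are TSVs with columns `triad_id`, `A`, `B`, `D` (configurable
via `column_map` in the API). Annotations are TSVs with `cell_id`,
`cluster` and optional `pseudotime`/`branch`/`segment`.

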