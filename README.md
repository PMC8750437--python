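# phasenet

Comparative transcriptome analysis of the three chronic myeloid leukemia
(CML) phases — chronic phase (CP), accelerated phase (AP) and blast crisis
(BC) — for computational biologists working with phase-labelled bulk
expression cohorts.  The package covers the full analysis chain:

1. **Normalization** of two-color microarray log-ratios (log10 → log2
   rescaling, quantile normalization across samples).
2. **Pairwise-phase differential expression** with empirical-Bayes moderated
   t-statistics and Storey q-values; expression-change calls at
   q ≤ 0.05 (optionally with an |log2FC| ≥ 1 magnitude cut); an
   accelerated-subtype check that decides whether the two AP definitions
   (blast count vs cytogenetic) can be merged.
3. **Functional-category enrichment** of under-/overexpressed gene sets with
   one-sided Fisher exact tests and Benjamini–Hochberg adjustment, plus
   per-pathway alteration profiles.
4. **Clustering and PCA**: sample PCA, 1 − r (Pearson) distance with Ward
   (ward.D2) hierarchical clustering of the signature heatmap, and
   resistant-vs-phase correlation analysis.
5. **Gene regulatory network inference** — the computational core.  Each
   signature gene is modeled as a sparse linear combination of all other
   signature genes.  Predictors enter along the LARS-lasso path and each
   entry is scored with the covariance test: for the predictor entering at
   knot λ_k,

   T_k = ( ⟨y, Xβ̂(λ_{k+1})⟩ − ⟨y, X_A β̃_A(λ_{k+1})⟩ ) / σ²,

   which is asymptotically Exp(1) under the null, so p = exp(−T).  Link
   p-values are pooled network-wide into Storey q-values; links at q ≤ 0.01
   define the gene models.  Inference is repeated over 100 random 75%/25%
   train/test splits; links present in ≥ 90 of 100 networks form the
   **consensus network**.  Held-out prediction quality (per-gene Pearson r
   between predicted and observed test expression) is benchmarked against
   degree-preserving random rewirings of the same networks.  Consensus genes
   with out-degree ≥ 3 are the **hub** candidates; each hub's sign pattern
   (s1, s2, s3) over the contrasts (AP vs CP, BC vs AP, BC vs CP) is
   classified as *toward-blast down*, *toward-blast up* or
   *accelerated-distinct*.

A seeded synthetic-data generator plants a ground-truth one-layer regulatory
network with phase-dependent mean shifts, so the whole chain is testable
without any external download.

## Worked example

```python
from phasenet import (SimulationConfig, make_ground_truth, simulate_expression,
                      run_pairwise, RegulatoryNetworkModel)

cfg = SimulationConfig(n_genes=60, n_hubs=5, out_degree_range=(3, 5), seed=11)
gt = make_ground_truth(cfg)                  # planted network + phase effects
matrix, meta = simulate_expression(gt, cfg)  # 60 genes x 87 samples (42/17/28)

de = run_pairwise(matrix, meta)              # three pairwise phase contrasts
print(de.summary())

model = RegulatoryNetworkModel(matrix, gene_set=de.signature)
results = model.fit(n_networks=20, min_support=18, seed=11)
print(results.summary())
print(results.hubs(de_tables=de.tables).to_string(index=False))
```

Output:

```
Pairwise-phase differential expression
  genes: 60   prior d0: 22.4   s0^2: 0.278
  cutoffs: q <= 0.05
  accelerated_vs_chronic: 41 called (20 under, 21 over)
  blast_vs_accelerated: 23 called (12 under, 11 over)
  blast_vs_chronic: 44 called (22 under, 22 over)
  signature size (union): 44

Consensus gene regulatory network
  genes: 44   networks: 20   support >= 18
  consensus edges: 22   hubs (out-degree >= 3): 3
  held-out prediction r: median 0.715 vs random 0.006 (one-sided U-test p = 2.28e-13)

 gene  out_degree s1 s2 s3       behavior_group
G0007           4  -  +  + accelerated_distinct
G0035           3  +  -  + accelerated_distinct
G0046           3  -  =  - accelerated_distinct
```

Reading the numbers: the three contrasts call 41/23/44 genes at q ≤ 0.05,
whose union (44 genes) is the expression signature.  The 20-network
consensus keeps 22 robust links; genes with ≥ 3 outgoing links are hubs.
The learned networks predict held-out expression far better than
degree-matched random networks (median r 0.715 vs 0.006) — the planted
regulatory structure carries real predictive information.  Each hub's sign
pattern over (AP vs CP, BC vs AP, BC vs CP) determines its phase-behavior
group.

The same analysis is scriptable end to end (`phasenet run --config
run.json`), and each stage has its own subcommand (`phasenet simulate`,
`normalize`, `de`, `enrich`, `network`); see `phasenet --help`.

## Layout

- `phasenet.io` — expression/metadata TSV I/O, log rescaling, quantile
  normalization
- `phasenet.simulate` — seeded synthetic cohorts with planted ground truth
- `phasenet.diffexpr` — moderated tests, Storey q-values, `run_pairwise`
- `phasenet.enrichment` — Fisher enrichment, GMT catalogs, pathway profiles
- `phasenet.cluster` — PCA, 1 − r ward.D2 clustering, resistant correlations
- `phasenet.network` — lasso-path + covariance-test inference,
  `RegulatoryNetworkModel` / `NetworkResults`, consensus, hubs
- `phasenet.pipeline` — end-to-end orchestration with a JSON manifest
- `docs/methods.md` — model assumptions, parameter choices, limitations
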