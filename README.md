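# tinnibench

A benchmark pipeline for **diagnostic-driven, semi-supervised clustering of
patient questionnaire data**, built around the subphenotyping problem in
tinnitus research: given a mixed quantitative/categorical patient table in
which only a small minority of patients carry an expert endotype diagnosis
(otosclerosis, Menière's disease, pulsatile tinnitus, ...), find the
clustering pipeline whose clusters best recover the known diagnoses while
remaining stable under resampling.

It is aimed at biostatisticians and clinical-data scientists who want to
compare dimensionality-reduction x clustering combinations on partially
labeled cohorts, and ship with a synthetic cohort generator so the entire
pipeline can be exercised and validated without access to any private
clinical database.

## What the pipeline does

1. **Preprocessing** — drop patients with more than 40% missing features,
   then features missing in more than 25% of the remaining patients (both
   cuts strict), then fill the remaining holes with MissForest-style
   iterative random-forest imputation.
2. **Partitioning** — three independent endotype-stratified 50-50
   train/test splits (every endotype, and the unlabeled group, balanced
   within one patient across the halves).
3. **Reduction** — PCA, factor analysis of mixed data (FAMD), or seeded
   t-SNE; each half of a partitioning is reduced independently with
   identical hyperparameters.
4. **Clustering** — k-means (squared Euclidean, best of 10 k-means++
   starts) or DBSCAN (noise label −1).
5. **Scoring** — three criteria per grid point, averaged over the three
   partitionings:
   * *V-measure* against the partial diagnoses, the weighted harmonic mean
     of homogeneity h and completeness c,

     V_β = (1 + β) · h · c / (β · h + c),  with β = 0.1,

     computed over labeled patients only;
   * *stability*: for k-means, the averaged adjusted mutual information

     AMI(U, V) = (MI(U, V) − E{MI}) / (max{H(U), H(V)} − E{MI})

     between the four clusterings obtained by fitting each half and
     cross-predicting the other (E{MI} by the exact hypergeometric sum);
     for DBSCAN, the train/test cluster-count difference;
   * *silhouette* mean (b − a)/max(a, b) in the clustering space.
6. **Selection** — eligibility filter (averaged AMI ≥ 0.7, or count
   difference 0 on every partitioning), shortlist by V-measure, then
   characterisation of the winning clustering: pooled Cohen's-D effect
   sizes of every feature for each cluster vs the rest, and the
   repartition of each endotype over clusters against a
   uniform-allocation null.

## Worked example

```python
import tinnibench as tb

spec = tb.make_separable_spec(n_patients=1200, seed=0)   # six planted endotypes
table, truth, observed = tb.generate_cohort(spec, seed=3)
splits = tb.stratified_splits(table.labels.to_numpy(object), seed=3)

grid = tb.GridSpec(reductions=("pca", "tsne"), clusterers=("kmeans",),
                   pca_components=(2,), tsne_components=(2,),
                   tsne_perplexity=(30,), kmeans_k=(6, 8, 10))
records = tb.run_benchmark(table, splits, grid, seed=3)
print(tb.benchmark_report(records).round(3))
```

prints one row per method combination with the three averaged criteria:

```
                     v_measure  stability  silhouette
reduction clusterer
pca       kmeans         0.837      0.611       0.333
tsne      kmeans         0.812      0.633       0.371
```

Here the best PCA + k-means grid point recovers the planted diagnoses
with V = 0.837 (clusters are largely diagnosis-pure), its four-clustering
AMI stability is 0.611 (below the 0.7 eligibility bar — halves of 600
patients are small for this), and the silhouette of 0.333 reflects
moderately compact clusters. Profiling the winning clustering then lists
each cluster's differentiating features, e.g.
`cluster 1 (n=95): scale_10 (0.66), scale_05 (0.59), scale_12 (0.53)`
— pooled Cohen's-D effect sizes vs the rest of the cohort — and the
endotype repartition shows e.g. 31 pulsatile-tinnitus patients observed
in one cluster where uniform random assignment would place 5.

The `examples/` directory holds one short narrative script per stage:
cohort generation, preprocessing, reduction + clustering, the stability
protocol, and the full benchmark with shortlisting and profiling. A thin
CLI mirrors the same stages (`tinnibench simulate | preprocess | bench |
profile`).

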