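"""Reduce a mixed cohort three ways and cluster the embeddings.

Encodes a separable synthetic cohort, projects it with PCA, FAMD and
t-SNE, clusters each embedding with k-means, and compares silhouettes —
the cohesion/separation score in the clustering space.
"""

import tinnibench as tb

spec = tb.make_separable_spec(n_patients=500, seed=0)
table, truth, _ = tb.generate_cohort(spec, seed=1)
encoded = tb.encode(table)

embeddings = {
    "pca": tb.reduce_pca(encoded, n_components=2),
    "famd": tb.reduce_famd(table, n_components=2),
    "tsne": tb.reduce_tsne(encoded, n_components=2, perplexity=30, seed=1),
}

print("silhouette of a k=7 k-means clustering in each embedding")
print("(higher = clusters are tighter and better separated):")
for name, emb in embeddings.items():
    _, assignment = tb.fit_kmeans(emb, k=7, seed=0)
    sil = tb.silhouette_mean(emb, assignment)
    print(f"  {name:5s} silhouette = {sil:.3f}")

dbscan = tb.fit_dbscan(embeddings["tsne"], eps=2.0, min_samples=4)
noise = int((dbscan.labels == -1).sum())
print(f"\nDBSCAN on the t-SNE map: {dbscan.n_clusters} clusters,"
      f" {noise} noise points (isolated low-density samples)")
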