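"""Embed traces in 2-D and cluster the embedding.

Runs the exact t-SNE implementation on a male cohort (each 1500-frame
trace is one point in R^1500), then K-means with K = 2...5 on the map,
printing the silhouette score and the purity of each clustering.  High
purity at K = 2 means the unsupervised map separates the genotypes.
"""

import numpy as np

from catrace import embed_tsne, generate_cohort, make_default_config
from catrace.cluster import cluster_with_scores

cohort = generate_cohort(make_default_config("male", seed=0))
# subsample for a quick demonstration
rng = np.random.default_rng(0)
keep = rng.choice(cohort.n_cells, size=200, replace=False)
sub = cohort.subset(np.sort(keep))

emb = embed_tsne(sub.values, perplexity=30, n_steps=500, seed=42)
print(f"t-SNE: KL {emb.objective_trace[0]:.3f} -> {emb.objective_trace[-1]:.3f}")

for k in (2, 3, 4, 5):
    res = cluster_with_scores(emb.coords, sub.labels, k, seed=0)
    print(f"  K={k}: silhouette {res.silhouette_overall:.3f}, "
          f"per-cluster purity {[round(float(p), 2) for p in res.purity]}")
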