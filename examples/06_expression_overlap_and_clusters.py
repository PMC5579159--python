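"""Cross-dataset integration: 5hmC/RNA direction overlap, in-silico
pooling, and K-means clustering of gene-level methylation change.
"""

import numpy as np
import pandas as pd

from dipkit import (
    SimParams,
    count_windows,
    gene_methylation_profiles,
    hmc_up_genes,
    kmeans_profiles,
    overlap_test,
    pool_in_silico,
    simulate_dipseq,
    simulate_genome,
    simulate_rnaseq,
)

params = SimParams(seed=1)
genome, genes = simulate_genome(params)
tags, truth = simulate_dipseq(params, genome=genome, genes=genes)
rna_counts, truth = simulate_rnaseq(params, genes, truth)

# direction-stratified overlap: genes with up-shifted 5hmC vs RNA-up genes
up5 = hmc_up_genes(genes, truth)
rna_up = {g for g, d in truth.de_genes if d == "up"}
res = overlap_test(up5, rna_up, [g.gene_id for g in genes], "5hmC_up", "RNA_up")
print(f"5hmC-up ∩ RNA-up: {res.n_overlap}/{res.n_a} vs {res.n_b} in universe "
      f"{res.universe_size}; OR = {res.odds_ratio:.1f}, Fisher p = {res.p:.2g}")

# in-silico pooling: replicates collapse losslessly
reps = [t for t in tags if t.mark == "5mC" and t.condition == "sham"]
pooled = pool_in_silico(reps)
assert count_windows(pooled, 1000, 500).all_counts().sum() == sum(
    count_windows(r, 1000, 500).all_counts().sum() for r in reps
)
print(f"pooled {len(reps)} replicates -> {pooled.n_tags} tags ({pooled.library_id})")

# K-means on simple per-gene change features (5hmC up?, RNA log-fold)
sham = rna_counts[[c for c in rna_counts if "sham" in c]].mean(axis=1)
irr = rna_counts[[c for c in rna_counts if "irradiated" in c]].mean(axis=1)
features = pd.DataFrame({
    "rna_log2fc": np.log2((irr + 0.5) / (sham + 0.5)),
    "hmc_up": [1.0 if g.gene_id in up5 else 0.0 for g in genes],
}, index=[g.gene_id for g in genes])
profiles = gene_methylation_profiles(list(features.index), features)
clustered, inertia = kmeans_profiles(profiles, k=4, n_starts=10, seed=0)
sizes = pd.Series([p.cluster for p in clustered]).value_counts().sort_index()
print("K-means cluster sizes (k=4):", sizes.tolist(), f"inertia = {inertia:.1f}")
# A significant Fisher p confirms the planted co-regulation of 5hmC
# gains and transcriptional up-regulation.
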