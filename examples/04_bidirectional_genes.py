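"""Detect bidirectional genes: both up- and down-regulated DHRs in one
gene body — and test their distal DHR density.

Reproduces the core analysis chain: DHR calling, gene-body assignment,
hypergeometric up/down overlap, 200 kb gene filter with four 50 kb
density bins, label-permutation density contrast, and the density vs
significance rank correlation.
"""

from dipkit import (
    SimParams,
    annotate_to_tss,
    assign_gene_classes,
    call_significant,
    count_tags_in_regions,
    density_vs_significance,
    dhr_density_bins,
    find_bidirectional_genes,
    merge_region_sets,
    nb_test,
    permutation_density_test,
    segment_tagset,
    simulate_dipseq,
    simulate_genome,
)

params = SimParams(seed=1)
genome, genes = simulate_genome(params)
tags, truth = simulate_dipseq(params, genome=genome, genes=genes)

hmc = [t for t in tags if t.mark == "5hmC"]
sets = [segment_tagset(t, n_permutations=50, alpha=1e-5, seed=30 + i)
        for i, t in enumerate(hmc)]
results = nb_test(count_tags_in_regions(hmc, merge_region_sets(sets)))

# permissive tier (p < 0.1) for the density analyses, strict for sets
up_strict, down_strict = call_significant(results, 0.01)
permissive = [r for r in results if r.p < 0.1]


def body_genes(regions):
    out = set()
    for r in regions:
        mid = r.interval.midpoint
        for g in genes:
            if g.chrom == r.interval.chrom and g.interval.start <= mid < g.interval.end:
                out.add(g.gene_id)
                break
    return out


res = find_bidirectional_genes(body_genes(up_strict), body_genes(down_strict), len(genes))
print(f"up genes: {len(res.up_genes)}, down genes: {len(res.down_genes)}, "
      f"bidirectional: {len(res.bidirectional_genes)} "
      f"(planted {len(truth.bidirectional_genes)}), overlap p = {res.overlap_p:.2g}")

annotations = annotate_to_tss(permissive, genes)
table = dhr_density_bins(genes, annotations, min_gene_length_bp=200_000,
                         bin_bp=50_000, n_bins=4)
labels = assign_gene_classes(table.index, res.up_genes, res.down_genes)
test = permutation_density_test(table, labels, ("bidirectional", "control"),
                                n_permutations=999, seed=5)
print("per-bin mean density difference (bidirectional - control):",
      [f"{d:+.2f}" for d in test.statistic_per_bin])
print("per-bin permutation p:", [f"{p:.3g}" for p in test.p_per_bin],
      f"| global p = {test.global_p:.3g}")

corr = density_vs_significance(genes, annotations, table)
print(f"density vs significance rank correlation: rho = {corr.rho:.2f}, p = {corr.p:.2g}")
# A small hypergeometric p and positive distal-bin differences mean the
# bidirectional class carries genuinely denser intragenic remodeling.
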