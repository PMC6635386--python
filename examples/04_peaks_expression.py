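"""Peak annotation and peak-expression-insulation association statistics.

Plants CTCF/cohesin-like peaks (80% in promoters) and an expression table
with a one-log2 promoter-peak effect, then recovers both: the annotation
frequencies, the compartment-occupancy enrichment, the rank-sum expression
difference, and a permutation Z-score of insulation at peaks.
"""

import numpy as np

from meiohic import (
    ArchitectureSpec,
    EffectSpec,
    GenomeSpec,
    annotate_peaks_to_features,
    build_genome_layout,
    call_compartments,
    compartment_occupancy_enrichment,
    counts_to_cpm,
    expression_group_comparison,
    filter_low_count_bins,
    hypergeometric_enrichment_bh,
    planted_compartment_labels,
    sample_contact_reads,
    simulate_expected_matrix,
    simulate_expression_table,
    simulate_peak_tracks,
)

layout, genes = build_genome_layout(GenomeSpec(), seed=2)
labels = planted_compartment_labels(layout)
effect = EffectSpec(seed=2)  # 500 peaks, 80% promoter, +1 log2 on peak genes

peaks = simulate_peak_tracks(layout, genes, effect)
cats, dists = annotate_peaks_to_features(peaks, genes)
print("peak annotation:", cats.value_counts().to_dict())
print(f"median |distance to nearest TSS|: {np.median(np.abs(dists)):,.0f} bp")

gene_bins = np.array(
    [layout.bin_index(c, int(t)) for c, t in zip(genes["chrom"], genes["tss"])]
)
flags = genes["gene_id"].isin(peaks.loc[peaks["promoter"], "gene_id"]).to_numpy()
expr = simulate_expression_table(genes, labels[gene_bins], flags, effect)

# genes with a promoter peak express higher than genes without
peak_genes = genes.loc[flags, "gene_id"].tolist()
rest = genes.loc[~flags, "gene_id"].tolist()
stat, p, direction = expression_group_comparison(expr, peak_genes, rest)
print(f"promoter-peak genes vs rest: rank-sum p = {p:.2e}, "
      f"direction {'+' if direction > 0 else '-'} (planted +1 log2 effect)")

# peak occupancy is biased toward the A compartment (gene-dense side)
_, raw = sample_contact_reads(
    simulate_expected_matrix(layout, ArchitectureSpec(seed=2), labels),
    1_000_000, seed=2,
)
gd = np.zeros(layout.n_bins)
for c, t in zip(genes["chrom"], genes["tss"]):
    gd[layout.bin_index(c, int(t))] += 1
profile = call_compartments(filter_low_count_bins(raw), gd)
frac_a, p_a = compartment_occupancy_enrichment(peaks, profile, n_perm=2_000,
                                               seed=2)
print(f"peaks in A compartment: {frac_a:.1%} (permutation p = {p_a:.4f})")

# CPM conversion and a toy GO enrichment of the top-expressed genes
cpm = counts_to_cpm(expr[["gene_id", "counts"]].rename(columns={"counts": "x"}))
print(f"CPM column sums to {cpm['x'].sum():,.0f}")
top = set(expr.nlargest(100, "fpkm")["gene_id"])
terms = {"peak_target_genes": set(peak_genes),
         "random_genes": set(genes["gene_id"][::7])}
res = hypergeometric_enrichment_bh(terms, top, set(genes["gene_id"]))
print(res[["term", "k", "K", "p", "q"]].to_string(index=False))
# peak-target genes are enriched among top expressers; random genes are not
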