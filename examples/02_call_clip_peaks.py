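"""Call CLIP-seq binding peaks against the per-gene Monte-Carlo null.

Plants one 60-bp binding site (20x background density) in half of 30
genes, simulates IP and input samples, and runs the full peak-calling
chain: cluster -> per-gene null -> empirical p -> input subtraction ->
target-gene assignment.
"""

from spliceclip import (
    GeneIndex,
    assign_targets,
    call_peaks,
    cluster_peaks,
    make_gene_models,
    make_peak_truths,
    simulate_clip,
    simulate_null,
    subtract_input,
)
from spliceclip.clip import peaks_to_frame

genes, _ = make_gene_models(30, seed=1)
truths = make_peak_truths(genes, frac_with_peak=0.5, enrichment=20.0, seed=2)
ip_reads, input_reads = simulate_clip(genes, truths, background_per_kb=10.0, seed=3)

index = GeneIndex(genes)
gene_by_id = {g.gene_id: g for g in genes}


def call_sample(reads, seed):
    by_gene = {}
    for r in reads:
        hits = index.containing_point(r.chrom, r.span.midpoint, r.strand)
        if hits:
            by_gene.setdefault(hits[0].gene_id, []).append(r)
    kept = []
    for gid in sorted(by_gene):
        peaks = cluster_peaks(by_gene[gid])
        # null: the gene's peak reads re-placed uniformly 500 times
        null = simulate_null(
            gene_by_id[gid], [r.span.length for r in by_gene[gid]], n_iter=500, seed=seed
        )
        kept.extend(call_peaks(peaks, null, alpha=0.05))
    return kept


final = subtract_input(call_sample(ip_reads, 4), call_sample(input_reads, 5))
final, targets = assign_targets(final, index)
print(peaks_to_frame(final).to_string(index=False))
# height = max per-base read depth in the cluster; p_emp < 0.05 means the
# observed height beat the random-placement null in >95% of iterations.
planted = {t.gene_id for t in truths}
print(f"\nplanted sites: {len(planted)}, target genes called: {len(targets)}, "
      f"recovered: {len(targets & planted)}")
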