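import numpy as np
import pytest

from spliceclip.genome_io import GenomicInterval, write_gtf
from spliceclip.splicing import extract_boundary_counts, extract_junctions
from spliceclip.synthetic import (
    AS_TYPES,
    PeakTruth,
    SpliceTruth,
    make_deg_truths,
    make_gene_models,
    make_peak_truths,
    make_splice_truths,
    simulate_clip,
    simulate_counts,
    simulate_rnaseq,
)


class TestMakeGeneModels:
    def test_all_types_present_and_valid(self):
        genes, bps = make_gene_models(10, seed=0)
        assert {bp.as_type for bp in bps.values()} == set(AS_TYPES)
        for g in genes:
            # genome_io invariants are enforced on construction; check the
            # extra structural promises: CDS and both UTRs present
            assert g.region_union("cds")
            assert g.region_union("5utr")
            assert g.region_union("3utr")
            for bp in [bps[g.gene_id]]:
                assert g.span.contains(bp.alt_region)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            make_gene_models(5, seed=0)

    def test_deterministic_annotation(self, tmp_path):
        a, b = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(make_gene_models(12, seed=7)[0], a)
        write_gtf(make_gene_models(12, seed=7)[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_alt_model_keys_disjoint(self):
        _, bps = make_gene_models(20, seed=3)
        for bp in bps.values():
            assert not (set(bp.alt_keys) & set(bp.model_keys))


class TestSimulateRnaseq:
    def test_ratio_one_gives_no_model_reads(self):
        genes, bps = make_gene_models(10, seed=1)
        truths = [
            SpliceTruth(f"{g}:{bps[g].as_type}", g, bps[g].as_type, 1.0, 1.0)
            for g in bps
        ]
        reads = simulate_rnaseq(genes, bps, truths, depth=50, n_reps=1, seed=2)
        jx = extract_junctions(r for rs in reads.values() for r in rs)
        model_jkeys = {
            (bp.chrom, bp.strand, k[3], k[4])
            for bp in bps.values()
            for k in bp.model_keys
            if k[0] == "J"
        }
        assert not (set(jx) & model_jkeys)

    def test_ratio_estimates_within_binomial_error(self):
        """Sample splicing ratios land within 3 binomial SEs of truth."""
        genes, bps = make_gene_models(10, seed=1)
        truths = make_splice_truths(bps, frac_differential=1.0, seed=3)
        depth = 200
        reads = simulate_rnaseq(genes, bps, truths, depth=depth, n_reps=2, seed=4)
        all_reads = [r for rs in reads.values() for r in rs]
        jx = extract_junctions(all_reads)
        bd = extract_boundary_counts(all_reads, genes)
        for t in truths:
            bp = bps[t.gene_id]
            for sample, true_r in (("ctrl_1", 0.9), ("kd_1", 0.3)):
                alt = model = 0
                for kind, chrom, strand, s, e in bp.alt_keys:
                    if kind == "J":
                        alt += jx.get((chrom, strand, s, e), {}).get(sample, 0)
                    else:
                        l, r = bd.get((chrom, strand, s, e), {}).get(sample, (0, 0))
                        alt += round((l + r) / 2)
                for kind, chrom, strand, s, e in bp.model_keys:
                    model += jx.get((chrom, strand, s, e), {}).get(sample, 0)
                est = alt / (alt + model)
                se = np.sqrt(true_r * (1 - true_r) / depth)
                assert abs(est - true_r) < 3 * se, (t.event_id, sample, est)

    def test_seed_reproducibility(self):
        genes, bps = make_gene_models(10, seed=1)
        truths = make_splice_truths(bps, seed=5)
        r1 = simulate_rnaseq(genes, bps, truths, depth=30, seed=9)
        r2 = simulate_rnaseq(genes, bps, truths, depth=30, seed=9)
        assert r1 == r2


class TestSimulateClip:
    def test_planted_peak_concentrates_reads(self):
        genes, _ = make_gene_models(10, seed=2)
        g = genes[0]
        iv = GenomicInterval(g.chrom, g.span.start + 500, g.span.start + 560, g.strand)
        truth = [PeakTruth(g.gene_id, iv, enrichment=20.0)]
        ip, inp = simulate_clip(genes, truth, background_per_kb=10.0, seed=3)
        in_peak = sum(1 for r in ip if r.span.overlaps(iv))
        # expected extra reads: 20 x 10/kb x 60bp = 12 on top of background
        bg_window = 10.0 * 60 / 1000  # 0.6 expected background reads
        assert in_peak > 5 * bg_window

    def test_peak_outside_gene_span_errors(self):
        genes, _ = make_gene_models(10, seed=2)
        g = genes[0]
        bad = GenomicInterval(g.chrom, g.span.end + 100, g.span.end + 200, g.strand)
        with pytest.raises(ValueError, match="outside span"):
            simulate_clip(genes, [PeakTruth(g.gene_id, bad, 5.0)], seed=0)

    def test_seed_reproducibility(self):
        genes, _ = make_gene_models(10, seed=2)
        pt = make_peak_truths(genes, seed=4)
        assert simulate_clip(genes, pt, seed=5) == simulate_clip(genes, pt, seed=5)

    def test_no_planting_matches_input_rate(self):
        genes, _ = make_gene_models(30, seed=6)
        ip, inp = simulate_clip(genes, [], background_per_kb=20.0, seed=7)
        # same generating process: totals agree within Poisson noise
        lam = sum(20.0 * g.span.length / 1000 for g in genes)
        assert abs(len(ip) - len(inp)) < 6 * np.sqrt(2 * lam)


class TestSimulateCounts:
    def test_null_genes_rarely_exceed_twofold(self):
        degs = make_deg_truths(
            3000, frac_de=0.0, baseline_mean=500.0, baseline_sigma=0.0, seed=0
        )
        counts = simulate_counts(degs, n_reps=3, seed=1)
        ctrl = counts[[c for c in counts if c.startswith("ctrl")]].mean(axis=1)
        kd = counts[[c for c in counts if c.startswith("kd")]].mean(axis=1)
        lfc = np.log2((kd + 1) / (ctrl + 1))
        assert (np.abs(lfc) > 1).mean() < 0.01

    def test_poisson_limit(self):
        degs = [
            d
            for d in make_deg_truths(
                2000, frac_de=0.0, baseline_mean=100.0, baseline_sigma=0.0,
                dispersion=0.0, seed=2,
            )
        ]
        counts = simulate_counts(degs, n_reps=3, seed=3).to_numpy().ravel()
        assert abs(counts.var() / counts.mean() - 1) < 0.1

    def test_library_scaling_and_determinism(self):
        degs = make_deg_truths(500, seed=4)
        c1 = simulate_counts(degs, n_reps=2, library_size=1e5, seed=5)
        c2 = simulate_counts(degs, n_reps=2, library_size=1e5, seed=5)
        assert c1.equals(c2)
        ctrl_sums = c1[[c for c in c1 if c.startswith("ctrl")]].sum()
        # column totals track the requested library size (3 SD of NB sum)
        assert np.all(np.abs(ctrl_sums - 1e5) < 3 * np.sqrt(1e5 * (1 + 0.05 * 1e5 / 500)))

    def test_needs_two_reps(self):
        with pytest.raises(ValueError):
            simulate_counts(make_deg_truths(10, seed=0), n_reps=1, seed=0)
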