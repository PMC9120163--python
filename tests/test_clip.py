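import numpy as np
import pytest

from _oracles import brute_force_clusters
from conftest import make_transcript
from spliceclip.clip import (
    NullDistribution,
    Peak,
    assign_targets,
    call_peaks,
    cluster_peaks,
    empirical_pvalue,
    kmer_enrichment,
    merge_replicate_peaks,
    metagene_profile,
    region_distribution,
    simulate_null,
    subtract_input,
)
from spliceclip.genome_io import AlignedRead, GeneModel, GenomicInterval


def read(rid, s, e, strand="+", chrom="chr1", sample="ip"):
    return AlignedRead(rid, sample, chrom, strand, (GenomicInterval(chrom, s, e, strand),))


class TestClusterPeaks:
    def test_examples(self):
        peaks = cluster_peaks([read("a", 0, 10), read("b", 5, 15), read("c", 20, 30)])
        assert [(p.interval.start, p.interval.end, p.height) for p in peaks] == [
            (0, 15, 2),
            (20, 30, 1),
        ]

    def test_stacked_reads(self):
        peaks = cluster_peaks([read(f"r{i}", 100, 130) for i in range(7)])
        assert len(peaks) == 1 and peaks[0].height == 7 and peaks[0].n_reads == 7

    def test_touching_reads_stay_separate(self):
        peaks = cluster_peaks([read("a", 0, 10), read("b", 10, 20)])
        assert len(peaks) == 2

    def test_strands_cluster_independently(self):
        peaks = cluster_peaks([read("a", 0, 10, "+"), read("b", 5, 15, "-")])
        assert len(peaks) == 2

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            spans = []
            for i in range(n):
                s = int(rng.integers(0, 1500))
                spans.append((s, s + int(rng.integers(10, 80))))
            got = cluster_peaks([read(f"r{i}", s, e) for i, (s, e) in enumerate(spans)])
            got = sorted(
                (p.interval.start, p.interval.end, p.n_reads, p.height) for p in got
            )
            assert got == brute_force_clusters(spans)


def one_span_gene(gid="g", start=0, end=10_000, strand="+", chrom="chr1"):
    third = (end - start) // 3
    t = make_transcript(
        "t_" + gid, gid, chrom, strand, [(start, end)], (start + third, end - third)
    )
    return GeneModel(gid, (t,))


class TestSimulateNull:
    def test_forced_placement(self):
        g = one_span_gene(end=30)
        null = simulate_null(g, [30, 30, 30], n_iter=200, seed=0)
        assert set(null.max_heights) == {3}

    def test_read_longer_than_span_errors(self):
        with pytest.raises(ValueError):
            simulate_null(one_span_gene(end=20), [30], n_iter=100, seed=0)

    def test_deterministic(self):
        g = one_span_gene()
        n1 = simulate_null(g, [30] * 10, n_iter=300, seed=5)
        n2 = simulate_null(g, [30] * 10, n_iter=300, seed=5)
        assert n1 == n2

    def test_two_read_overlap_probability(self):
        """P(two length-L reads overlap in a span of S placeable starts)
        equals the exact discrete value; checked to Monte-Carlo error."""
        g = one_span_gene(end=1000)
        L, starts = 10, 991
        exact = (2 * sum(starts - d for d in range(1, L)) + starts) / starts**2
        null = simulate_null(g, [L, L], n_iter=8000, seed=1)
        obs = sum(1 for h in null.max_heights if h == 2) / null.n_iter
        tol = 4 * np.sqrt(exact * (1 - exact) / null.n_iter)
        assert abs(obs - exact) < tol


class TestCallPeaks:
    def peak(self, h):
        return Peak(GenomicInterval("chr1", 0, 50, "+"), max(h, 1), h)

    def test_pseudocount_formula(self):
        null = NullDistribution("g", tuple([2] * 500))
        kept = call_peaks([self.peak(5)], null)
        assert kept and kept[0].p_emp == pytest.approx(1 / 501)
        assert call_peaks([self.peak(1)], null) == []  # p = 1.0
        assert empirical_pvalue(1, null) == 1.0

    def test_borderline_count(self):
        null = NullDistribution("g", tuple([9] * 25 + [1] * 475))
        # exceeded-or-tied in 25 iterations: p = 26/501 > 0.05
        assert call_peaks([self.peak(9)], null) == []
        assert empirical_pvalue(9, null) == pytest.approx(26 / 501)

    def test_needs_iterations(self):
        with pytest.raises(ValueError):
            call_peaks([self.peak(5)], NullDistribution("g", (1,) * 50))


class TestSubtractAssign:
    def p(self, s, e, strand="+"):
        return Peak(GenomicInterval("chr1", s, e, strand), 1, 1)

    def test_overlap_removes_touching_keeps(self):
        assert subtract_input([self.p(100, 150)], [self.p(140, 200)]) == []
        assert subtract_input([self.p(100, 150)], [self.p(150, 200)]) == [self.p(100, 150)]
        assert subtract_input([self.p(100, 150)], []) == [self.p(100, 150)]

    def test_idempotent(self):
        ip = [self.p(0, 50), self.p(100, 150), self.p(300, 400)]
        inp = [self.p(40, 60)]
        once = subtract_input(ip, inp)
        assert subtract_input(once, inp) == once

    def test_assign_targets(self):
        g = one_span_gene("gene1", 0, 1000)
        peaks = [self.p(100, 200), self.p(5000, 5100), self.p(300, 400)]
        out, targets = assign_targets(peaks, [g])
        assert [p.gene_id for p in out] == ["gene1", None, "gene1"]
        assert targets == {"gene1"}

    def test_replicate_merge(self):
        m = merge_replicate_peaks([self.p(0, 50), self.p(200, 250)], [self.p(40, 90)])
        assert [(p.interval.start, p.interval.end) for p in m] == [(0, 90)]


class TestProfiles:
    def test_region_distribution_sums_to_one(self):
        g = one_span_gene("g", 0, 3000)
        reads = [read(f"r{i}", 100 * i, 100 * i + 30) for i in range(25)]
        dist = region_distribution(reads, [g])
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert region_distribution([], [g]) == {}

    def test_metagene_center_and_conservation(self):
        # single-exon gene: 5utr [0,1000), cds [1000,2000), 3utr [2000,3000)
        t = make_transcript("t", "g", "chr1", "+", [(0, 3000)], (1000, 2000))
        g = GeneModel("g", (t,))
        center_read = read("r", 1485, 1515)  # midpoint 1500 = CDS center
        prof = metagene_profile([center_read], [g])
        cds = prof[prof.region == "cds"].set_index("bin")["count"]
        assert cds.loc[50] == 1 and cds.sum() == 1
        many = [read(f"r{i}", 10 * i, 10 * i + 30) for i in range(290)]
        prof = metagene_profile(many, [g])
        in_regions = sum(1 for r in many if 0 <= r.span.midpoint < 3000)
        assert prof["count"].sum() == in_regions

    def test_minus_strand_mirrors(self):
        tp = make_transcript("tp", "gp", "chr1", "+", [(0, 3000)], (1000, 2000))
        tm = make_transcript("tm", "gm", "chr2", "-", [(0, 3000)], (1000, 2000))
        gp, gm = GeneModel("gp", (tp,)), GeneModel("gm", (tm,))
        rp = read("rp", 1100, 1130, "+", "chr1")  # CDS offset 115 of 1000
        rm = read("rm", 1870, 1900, "-", "chr2")  # mirrored position
        pp = metagene_profile([rp], [gp])
        pm = metagene_profile([rm], [gm])
        bp = pp[(pp.region == "cds") & (pp["count"] > 0)]["bin"].item()
        bm = pm[(pm.region == "cds") & (pm["count"] > 0)]["bin"].item()
        assert bp == bm == 11

    def test_gene_without_cds_excluded(self, caplog):
        t = make_transcript("t", "g", "chr1", "+", [(0, 3000)])
        with caplog.at_level("INFO"):
            prof = metagene_profile([read("r", 10, 40)], [GeneModel("g", (t,))])
        assert prof["count"].sum() == 0


class TestKmerEnrichment:
    def test_cu_repeat_tops_table(self):
        rng = np.random.default_rng(0)
        bg = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(60)]
        peaks = ["CUCUCUCUCUCUCUCU"] * 30
        table = kmer_enrichment(peaks, bg, k=5)
        assert table.iloc[0]["kmer"] in {"CTCTC", "TCTCT"}
        assert table.iloc[0]["fold"] > 10

    def test_identical_sets_fold_one(self):
        seqs = ["ACGTACGTAC", "GGGTTTAAAC"]
        table = kmer_enrichment(seqs, seqs, k=4)
        assert np.allclose(table["fold"], 1.0)

    def test_k_longer_than_sequence(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGT"], ["ACGT"], k=5)
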