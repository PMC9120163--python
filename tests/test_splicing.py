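import numpy as np
import pytest
from scipy import stats

from conftest import make_transcript
from spliceclip.genome_io import AlignedRead, GeneModel, GenomicInterval
from spliceclip.splicing import (
    ASEQuant,
    call_rases,
    detect_as_events,
    extract_boundary_counts,
    extract_junctions,
    filter_events,
    quantify_events,
    summarize_rase,
)
from spliceclip.splicing import test_rase_fisher as fisher_call
from spliceclip.splicing import test_rase_ttest as ttest_call
from spliceclip.synthetic import (
    AS_TYPES,
    make_gene_models,
    make_splice_truths,
    simulate_rnaseq,
)


def spliced_read(rid, sample, s1, e1, s2, e2, strand="+", chrom="chr1"):
    return AlignedRead(
        rid,
        sample,
        chrom,
        strand,
        (
            GenomicInterval(chrom, s1, e1, strand),
            GenomicInterval(chrom, s2, e2, strand),
        ),
    )


class TestExtractJunctions:
    def test_single_read(self):
        jx = extract_junctions([spliced_read("r1", "s1", 1000, 1050, 1150, 1200)])
        assert jx == {("chr1", "+", 1050, 1150): {"s1": 1}}

    def test_per_sample_counts(self):
        jx = extract_junctions(
            [
                spliced_read("r1", "s1", 0, 50, 100, 150),
                spliced_read("r2", "s2", 0, 50, 100, 150),
            ]
        )
        assert jx[("chr1", "+", 50, 100)] == {"s1": 1, "s2": 1}

    def test_unspliced_reads_yield_nothing(self):
        r = AlignedRead("r", "s", "chr1", "+", (GenomicInterval("chr1", 0, 100, "+"),))
        assert extract_junctions([r]) == {}


class TestDetectFromAnnotation:
    """Hand-built minimal genes exercising the construction rules."""

    def test_a5ss_from_shared_acceptor(self):
        # two junctions sharing the acceptor end, donors 10 bp apart, plus
        g = GeneModel(
            "g",
            (
                make_transcript("t1", "g", "chr1", "+", [(0, 100), (200, 300)], (10, 290)),
                make_transcript("t2", "g", "chr1", "+", [(0, 110), (200, 300)], (10, 290)),
            ),
        )
        jx = {("chr1", "+", 100, 200): {"s": 5}, ("chr1", "+", 110, 200): {"s": 5}}
        events = detect_as_events([g], jx)
        assert [e.as_type for e in events] == ["A5SS"]
        (e,) = events
        assert e.model_support == (("J", "chr1", "+", 100, 200),)
        assert e.alt_support == (("J", "chr1", "+", 110, 200),)

    def test_es_from_skip_junction(self):
        g = GeneModel(
            "g",
            (
                make_transcript(
                    "t1", "g", "chr1", "+",
                    [(0, 100), (200, 300), (400, 500)], (10, 490),
                ),
            ),
        )
        jx = {
            ("chr1", "+", 100, 200): {"s": 5},
            ("chr1", "+", 300, 400): {"s": 5},
            ("chr1", "+", 100, 400): {"s": 3},  # novel skip of exon 2
        }
        events = detect_as_events([g], jx)
        assert [e.as_type for e in events] == ["ES"]
        (e,) = events
        assert e.alt_support == (("J", "chr1", "+", 100, 400),)
        assert set(e.model_support) == {
            ("J", "chr1", "+", 100, 200),
            ("J", "chr1", "+", 300, 400),
        }

    def test_intronr_from_boundary_reads(self):
        g = GeneModel(
            "g",
            (make_transcript("t1", "g", "chr1", "+", [(0, 100), (200, 300)], (10, 290)),),
        )
        jx = {("chr1", "+", 100, 200): {"s": 8}}
        bd = {("chr1", "+", 100, 200): {"s": (4, 4)}}
        events = detect_as_events([g], jx, bd)
        assert [e.as_type for e in events] == ["IntronR"]
        (e,) = events
        assert e.alt_support == (("B", "chr1", "+", 100, 200),)
        assert e.model_support == (("J", "chr1", "+", 100, 200),)

    def test_junction_spanning_two_genes_unassigned(self):
        g1 = GeneModel(
            "a", (make_transcript("ta", "a", "chr1", "+", [(0, 100), (200, 300)]),)
        )
        g2 = GeneModel(
            "b", (make_transcript("tb", "b", "chr1", "+", [(0, 150), (250, 300)]),)
        )
        jx = {("chr1", "+", 100, 200): {"s": 5}}
        assert detect_as_events([g1, g2], jx) == []


class TestDetectAllTenTypes:
    @pytest.mark.parametrize("as_type", AS_TYPES)
    def test_planted_event_recovered_exactly(self, as_type):
        """Each generated gene template yields exactly its intended event,
        with the planted alt/model evidence keys, on both strands."""
        genes, bps = make_gene_models(20, seed=11)  # two genes per type (+/-)
        truths = make_splice_truths(bps, frac_differential=1.0, seed=12)
        reads = simulate_rnaseq(genes, bps, truths, depth=150, n_reps=1, seed=13)
        all_reads = [r for rs in reads.values() for r in rs]
        jx = extract_junctions(all_reads)
        bd = extract_boundary_counts(all_reads, genes)
        events = detect_as_events(genes, jx, bd)
        wanted = [bp for bp in bps.values() if bp.as_type == as_type]
        assert len(wanted) == 2 and {bp.strand for bp in wanted} == {"+", "-"}
        for bp in wanted:
            matches = [
                e
                for e in events
                if e.gene_id == bp.gene_id and e.as_type == as_type
                and set(e.alt_support) == set(bp.alt_keys)
            ]
            assert len(matches) == 1, f"{bp.gene_id} ({bp.strand})"
            assert set(matches[0].model_support) == set(bp.model_keys)


class TestFilterEvents:
    def ev(self):
        genes, bps = make_gene_models(10, seed=0)
        bp = bps["G0001"]
        from spliceclip.splicing import ASEvent

        return ASEvent("e1", "G0001", bp.as_type, bp.alt_keys, bp.model_keys, bp.alt_region)

    def quants(self, totals):
        return [ASEQuant("e1", f"s{i}", t, 0) for i, t in enumerate(totals)]

    @pytest.mark.parametrize(
        "totals,kept",
        [
            ((12, 15, 9, 11), False),  # 3/4 = 0.75 < 0.8
            ((12, 15, 10, 11), True),
            ((0, 50, 50, 50), False),  # not detectable in all samples
        ],
    )
    def test_examples(self, totals, kept):
        ev = self.ev()
        out = filter_events([ev], self.quants(totals))
        assert (len(out) == 1) is kept

    def test_monotone_in_min_reads(self):
        ev = self.ev()
        rng = np.random.default_rng(0)
        for _ in range(20):
            totals = tuple(int(x) for x in rng.integers(0, 30, size=5))
            kept_strict = filter_events([ev], self.quants(totals), min_reads=12)
            kept_loose = filter_events([ev], self.quants(totals), min_reads=8)
            if kept_strict:
                assert kept_loose


class TestFisher:
    def q(self, eid, s, alt, model):
        return ASEQuant(eid, s, alt, model)

    def test_extreme_table_matches_enumeration(self):
        from _oracles import fisher_two_sided_exact
        from math import comb

        call = fisher_call(self.q("e", "a", 10, 0), self.q("e", "b", 0, 10))
        assert call.rase_ratio == 1.0
        assert call.significant
        expected = 2 / comb(20, 10)
        assert call.pvalue == pytest.approx(expected, rel=1e-9)
        assert fisher_two_sided_exact(10, 0, 0, 10) == pytest.approx(expected, rel=1e-12)

    def test_identical_samples(self):
        call = fisher_call(self.q("e", "a", 5, 5), self.q("e", "b", 5, 5))
        assert call.rase_ratio == 0.0 and call.pvalue == 1.0 and not call.significant

    def test_ratio_boundary_decided_by_p(self):
        call = fisher_call(self.q("e", "a", 6, 4), self.q("e", "b", 4, 6))
        assert call.rase_ratio == pytest.approx(0.2)
        # at the 0.2 boundary the ratio filter passes; p decides (here ~0.66)
        assert not call.significant and call.pvalue > 0.05

    def test_empty_sample_excluded(self):
        assert fisher_call(self.q("e", "a", 0, 0), self.q("e", "b", 5, 5)) is None

    def test_label_swap_equivariance(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a1, m1, a2, m2 = (int(x) for x in rng.integers(0, 20, size=4))
            if (a1 + m1) == 0 or (a2 + m2) == 0:
                continue
            c = fisher_call(self.q("e", "a", a1, m1), self.q("e", "b", a2, m2))
            cs = fisher_call(self.q("e", "a", m1, a1), self.q("e", "b", m2, a2))
            assert c.pvalue == pytest.approx(cs.pvalue, rel=1e-9)
            assert c.rase_ratio == pytest.approx(cs.rase_ratio, abs=1e-12)


class TestTTest:
    def g(self, eid, ratios, prefix):
        return [
            ASEQuant(eid, f"{prefix}{i}", int(r * 100), 100 - int(r * 100))
            for i, r in enumerate(ratios)
        ]

    def test_identical_groups(self):
        c = ttest_call(self.g("e", [0.5, 0.5], "c"), self.g("e", [0.5, 0.5], "k"))
        assert c.rase_ratio == 0.0 and c.pvalue == 1.0 and not c.significant

    def test_hand_computed_pooled_t(self):
        # ratios (0.9, 0.8) vs (0.2, 0.3): sp^2 = 0.005, t = 0.6/sqrt(0.005) = 8.4853, df 2
        c = ttest_call(self.g("e", [0.9, 0.8], "c"), self.g("e", [0.2, 0.3], "k"))
        t = 0.6 / np.sqrt(0.005)
        expected_p = 2 * stats.t.sf(t, df=2)
        assert c.pvalue == pytest.approx(expected_p, rel=1e-9)
        assert c.significant and c.direction == "down"

    def test_group_of_one_errors(self):
        with pytest.raises(ValueError):
            ttest_call(self.g("e", [0.5], "c"), self.g("e", [0.5, 0.5], "k"))

    def test_zero_variance_unequal_means(self):
        c = ttest_call(self.g("e", [0.8, 0.8], "c"), self.g("e", [0.2, 0.2], "k"))
        assert c.pvalue == 0.0 and c.significant


class TestSummarize:
    def test_counts_and_conservation(self):
        genes, bps = make_gene_models(30, seed=21)
        truths = make_splice_truths(bps, frac_differential=0.6, seed=22)
        reads = simulate_rnaseq(genes, bps, truths, depth=200, n_reps=2, seed=23)
        all_reads = [r for rs in reads.values() for r in rs]
        jx = extract_junctions(all_reads)
        bd = extract_boundary_counts(all_reads, genes)
        events = detect_as_events(genes, jx, bd)
        quants = quantify_events(events, jx, bd)
        calls = call_rases(events, quants, ["ctrl_1", "ctrl_2"], ["kd_1", "kd_2"])
        table = summarize_rase(calls)
        assert table.to_numpy().sum() == sum(c.significant for c in calls)

    def test_empty(self):
        assert summarize_rase([]).empty
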