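"""Detection and statistical testing of alternative-splicing events from
splice-junction evidence.

The ten supported event types (ES, A5SS, A3SS, IntronR, MXE, 5pMXE, 3pMXE,
CassetteExon, A3SS&ES, A5SS&ES) are constructed from the observed junction
table against the annotation:

* A5SS / A3SS: two junctions sharing one end and differing at the donor or
  acceptor end respectively (strand-aware naming), with no annotated exon
  in the differing region; the annotated junction is the model.
* ES: a junction connecting non-adjacent annotated exon boundaries with at
  least one annotated exon fully inside, while the annotated inclusion
  junctions exist (alt = skipping junction, model = inclusion junctions).
* CassetteExon: inclusion of an exon absent from the annotation, evidenced
  by two novel junctions into/out of an interval inside an annotated
  intron (alt = inclusion junctions, model = the spanning junction).
* IntronR: alt = exon-intron boundary-spanning reads (>= 1 base on each
  side, the two boundaries averaged), model = the intron's junction reads.
* MXE: two exons each included only without the other, from four
  junctions between common flanks; 5pMXE / 3pMXE when both alternative
  exons lie in the annotated 5'/3' UTR.
* A3SS&ES / A5SS&ES: an alternative splice-site junction that
  simultaneously skips >= 1 annotated exon.

Per-sample splicing ratio is r = alt/(alt+model); the RASE ratio of an
event is the absolute between-group difference of mean r, and lies in
[0,1] so the 0.2 threshold is meaningful.  Significance uses Fisher's
exact test (two-sided) for pairwise comparisons and the pooled-variance
two-sample Student t-test for replicated designs; for Fisher calls, both
p <= 0.05 and RASE ratio >= 0.2 are required, for t-test calls p <= 0.05
alone.  For IntronR, higher retention in the treatment group is reported
as direction "up".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import AlignedRead, GeneIndex, GeneModel, GenomicInterval
from .synthetic import AS_TYPES, BKEY, JKEY  # canonical type/key vocabulary

logger = logging.getLogger(__name__)

JunctionKey = tuple[str, str, int, int]  # (chrom, strand, donor, acceptor)
JunctionTable = dict[JunctionKey, dict[str, int]]
BoundaryTable = dict[JunctionKey, dict[str, tuple[int, int]]]


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event with its evidence keys.

    Keys are ("J", chrom, strand, start, end) for junction reads and
    ("B", chrom, strand, start, end) for the boundary reads of a retained
    intron; alt and model key sets are disjoint.
    """

    event_id: str
    gene_id: str
    as_type: str
    alt_support: tuple[tuple, ...]
    model_support: tuple[tuple, ...]
    alt_region: GenomicInterval

    def __post_init__(self) -> None:
        if set(self.alt_support) & set(self.model_support):
            raise ValueError(f"{self.event_id}: alt and model support overlap")
        if self.as_type not in AS_TYPES:
            raise ValueError(f"{self.event_id}: unknown AS type {self.as_type}")


@dataclass(frozen=True)
class ASEQuant:
    """Per-sample quantification of one event."""

    event_id: str
    sample_id: str
    alt_reads: int
    model_reads: int

    @property
    def ratio(self) -> Optional[float]:
        total = self.alt_reads + self.model_reads
        return self.alt_reads / total if total else None


@dataclass(frozen=True)
class RASECall:
    """Result of testing one event for regulated splicing."""

    event_id: str
    as_type: str
    rase_ratio: float
    pvalue: float
    method: str  # fisher | ttest
    significant: bool
    direction: str  # up | down (treatment relative to control)


# ---------------------------------------------------------------------------
# evidence extraction
# ---------------------------------------------------------------------------


def extract_junctions(reads: Iterable[AlignedRead]) -> JunctionTable:
    """Count splice-junction support per (chrom, strand, donor, acceptor)
    and sample; each block gap of a spliced read increments one junction."""
    table: JunctionTable = {}
    for r in reads:
        for s, e in r.junctions:
            key = (r.chrom, r.strand, s, e)
            per = table.setdefault(key, {})
            per[r.sample_id] = per.get(r.sample_id, 0) + 1
    return {k: table[k] for k in sorted(table)}


def extract_boundary_counts(
    reads: Iterable[AlignedRead], genes: Sequence[GeneModel]
) -> BoundaryTable:
    """Count reads spanning each annotated intron's exon-intron boundaries.

    A read block spans a boundary at position p when it covers at least one
    base on each side (block.start < p < block.end).  Junction reads, whose
    blocks end exactly at the boundary, do not count.  Values are per-sample
    (5' boundary count, 3' boundary count) pairs in genomic order.
    """
    positions: dict[tuple[str, str], list[tuple[int, JunctionKey, int]]] = {}
    for g in genes:
        for (s, e) in g.annotated_introns:
            key = (g.chrom, g.strand, s, e)
            positions.setdefault((g.chrom, g.strand), []).append((s, key, 0))
            positions.setdefault((g.chrom, g.strand), []).append((e, key, 1))
    arrays = {}
    for k, items in positions.items():
        items.sort()
        arrays[k] = (np.array([p for p, _, _ in items]), items)

    table: BoundaryTable = {}
    for r in reads:
        entry = arrays.get((r.chrom, r.strand))
        if entry is None:
            continue
        pos_arr, items = entry
        for b in r.blocks:
            lo = int(np.searchsorted(pos_arr, b.start, side="right"))
            hi = int(np.searchsorted(pos_arr, b.end, side="left"))
            for i in range(lo, hi):
                p, key, side = items[i]
                if b.start < p < b.end:
                    per = table.setdefault(key, {})
                    pair = list(per.get(r.sample_id, (0, 0)))
                    pair[side] += 1
                    per[r.sample_id] = (pair[0], pair[1])
    return {k: table[k] for k in sorted(table)}


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def _assign_junctions_to_genes(
    genes: Sequence[GeneModel], junctions: JunctionTable
) -> dict[str, list[tuple[int, int]]]:
    index = GeneIndex(genes)
    per_gene: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}
    for (chrom, strand, s, e) in junctions:
        hits = [
            g
            for g in index.overlapping(chrom, s, e)
            if g.strand == strand and g.span.start <= s and e <= g.span.end
        ]
        if len(hits) == 1:
            per_gene[hits[0].gene_id].append((s, e))
        elif len(hits) > 1:
            logger.info("junction %s:%d-%d spans %d genes, unassigned", chrom, s, e, len(hits))
    return per_gene


def detect_as_events(
    genes: Sequence[GeneModel],
    junctions: JunctionTable,
    boundary_counts: Optional[BoundaryTable] = None,
) -> list[ASEvent]:
    """Construct all supported event types from observed junction evidence.

    Junctions contained in exactly one gene (matching strand) are
    considered for that gene; junctions consistent with several genes are
    assigned to none.  Detection is deterministic given its inputs.
    """
    boundary_counts = boundary_counts or {}
    per_gene = _assign_junctions_to_genes(genes, junctions)
    events: list[ASEvent] = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        events.extend(_detect_in_gene(g, per_gene[g.gene_id], boundary_counts))
    return events


def _detect_in_gene(
    g: GeneModel, obs: list[tuple[int, int]], boundary_counts: BoundaryTable
) -> list[ASEvent]:
    chrom, strand = g.chrom, g.strand
    ann = g.annotated_introns  # (s, e) -> first transcript index
    donors = {s for s, _ in ann}
    acceptors = {e for _, e in ann}
    ann_exons = g.annotated_exons
    exon_of_tx: dict[tuple[int, int], int] = {}
    for i, t in enumerate(g.transcripts):
        for e in t.exons:
            exon_of_tx.setdefault((e.start, e.end), i)
    obs = sorted(set(obs))
    obs_set = set(obs)
    consumed: set[tuple[int, int]] = set()
    found: list[tuple[str, tuple, tuple, tuple[int, int]]] = []

    def exons_inside(s: int, e: int) -> list[GenomicInterval]:
        return [x for x in ann_exons if s <= x.start and x.end <= e]

    def jkey(s: int, e: int) -> tuple:
        return (JKEY, chrom, strand, s, e)

    def bkey(s: int, e: int) -> tuple:
        return (BKEY, chrom, strand, s, e)

    # --- cassette exons: novel junction pairs inside an annotated intron
    for (is_, ie) in sorted(ann):
        if exons_inside(is_, ie):
            continue
        outs = [(s, e) for (s, e) in obs if s == is_ and e < ie and (s, e) not in ann]
        ins = [(s, e) for (s, e) in obs if e == ie and s > is_ and (s, e) not in ann]
        for o in outs:
            for i in ins:
                if o[1] < i[0]:
                    found.append(
                        (
                            "CassetteExon",
                            (jkey(*o), jkey(*i)),
                            (jkey(is_, ie),),
                            (o[1], i[0]),
                        )
                    )
                    consumed.update((o, i))

    # --- mutually exclusive exons: two exon paths between common flanks
    paths: dict[tuple[int, int], list[GenomicInterval]] = {}
    for x in ann_exons:
        ins = [(s, e) for (s, e) in obs if e == x.start]
        outs = [(s, e) for (s, e) in obs if s == x.end]
        for (d, _) in ins:
            for (_, a) in outs:
                paths.setdefault((d, a), []).append(x)
    utr5 = g.region_union("5utr")
    utr3 = g.region_union("3utr")
    for (d, a), exons in sorted(paths.items()):
        if (d, a) in obs_set:
            continue  # a direct junction makes this an ES pattern instead
        exons = sorted(set(exons), key=lambda x: x.start)
        for i in range(len(exons)):
            for j in range(i + 1, len(exons)):
                A, B = exons[i], exons[j]
                if A.end > B.start or (A.end, B.start) in obs_set:
                    continue
                in_utr5 = all(
                    any(u.contains(x) for u in utr5) for x in (A, B)
                )
                in_utr3 = all(
                    any(u.contains(x) for u in utr3) for x in (A, B)
                )
                as_type = "5pMXE" if in_utr5 else "3pMXE" if in_utr3 else "MXE"
                ta = exon_of_tx.get((A.start, A.end), len(g.transcripts))
                tb = exon_of_tx.get((B.start, B.end), len(g.transcripts))
                model_x, alt_x = (A, B) if ta <= tb else (B, A)
                found.append(
                    (
                        as_type,
                        (jkey(d, alt_x.start), jkey(alt_x.end, a)),
                        (jkey(d, model_x.start), jkey(model_x.end, a)),
                        (alt_x.start, alt_x.end),
                    )
                )
                for jj in ((d, A.start), (A.end, a), (d, B.start), (B.end, a)):
                    consumed.add(jj)

    # --- exon skipping and combined splice-site/skipping events
    for (s, e) in obs:
        if (s, e) in consumed:
            continue
        ein = exons_inside(s, e)
        if not ein:
            continue
        model = sorted(
            (is_, ie) for (is_, ie) in ann if s <= is_ < ie <= e and (is_, ie) != (s, e)
        )
        start_ann, end_ann = s in donors, e in acceptors
        if (s, e) in ann or (start_ann and end_ann):
            if len(model) >= 2:
                found.append(
                    (
                        "ES",
                        (jkey(s, e),),
                        tuple(jkey(*m) for m in model),
                        (ein[0].start, ein[-1].end),
                    )
                )
                consumed.add((s, e))
        elif start_ann or end_ann:
            if not model:
                continue
            # the novel end is an alternative splice site; name it by the
            # biological side it alters
            novel_at_end = start_ann
            if strand == "+":
                as_type = "A3SS&ES" if novel_at_end else "A5SS&ES"
            else:
                as_type = "A5SS&ES" if novel_at_end else "A3SS&ES"
            found.append(
                (as_type, (jkey(s, e),), tuple(jkey(*m) for m in model), (s, e))
            )
            consumed.add((s, e))

    # --- alternative 5'/3' splice sites: junction pairs sharing one end
    remaining = [j for j in obs if j not in consumed]
    by_start: dict[int, list[int]] = {}
    by_end: dict[int, list[int]] = {}
    for (s, e) in remaining:
        by_start.setdefault(s, []).append(e)
        by_end.setdefault(e, []).append(s)

    def ss_event(j1: tuple[int, int], j2: tuple[int, int], diff: tuple[int, int], shared: str):
        a1, a2 = j1 in ann, j2 in ann
        if not (a1 or a2):
            return
        if exons_inside(*diff):
            return
        if a1 and a2:
            model_j = j1 if ann[j1] <= ann[j2] else j2
        else:
            model_j = j1 if a1 else j2
        alt_j = j2 if model_j == j1 else j1
        if shared == "start":  # acceptor ends differ (genomic)
            as_type = "A3SS" if strand == "+" else "A5SS"
        else:
            as_type = "A5SS" if strand == "+" else "A3SS"
        found.append((as_type, (jkey(*alt_j),), (jkey(*model_j),), diff))

    for s, ends in sorted(by_start.items()):
        ends = sorted(set(ends))
        for i in range(len(ends)):
            for j in range(i + 1, len(ends)):
                ss_event((s, ends[i]), (s, ends[j]), (ends[i], ends[j]), "start")
    for e, starts in sorted(by_end.items()):
        starts = sorted(set(starts))
        for i in range(len(starts)):
            for j in range(i + 1, len(starts)):
                ss_event((starts[i], e), (starts[j], e), (starts[i], starts[j]), "end")

    # --- intron retention: boundary-spanning reads over an annotated intron
    for (is_, ie) in sorted(ann):
        if exons_inside(is_, ie):
            continue
        key = (chrom, strand, is_, ie)
        per = boundary_counts.get(key, {})
        if any(l + r > 0 for (l, r) in per.values()):
            found.append(("IntronR", (bkey(is_, ie),), (jkey(is_, ie),), (is_, ie)))

    found.sort(key=lambda f: (f[3][0], f[3][1], f[0]))
    events = []
    seen = set()
    for k, (as_type, alt, model, region) in enumerate(found):
        sig = (as_type, alt)
        if sig in seen:
            continue
        seen.add(sig)
        events.append(
            ASEvent(
                event_id=f"{g.gene_id}:{as_type}:{region[0]}-{region[1]}",
                gene_id=g.gene_id,
                as_type=as_type,
                alt_support=alt,
                model_support=model,
                alt_region=GenomicInterval(chrom, region[0], region[1], strand),
            )
        )
    return events


# ---------------------------------------------------------------------------
# quantification, filtering
# ---------------------------------------------------------------------------


def _key_count(key: tuple, sample: str, junctions: JunctionTable, boundaries: BoundaryTable) -> int:
    kind, chrom, strand, s, e = key
    if kind == JKEY:
        return junctions.get((chrom, strand, s, e), {}).get(sample, 0)
    left, right = boundaries.get((chrom, strand, s, e), {}).get(sample, (0, 0))
    return int(round((left + right) / 2))


def quantify_events(
    events: Sequence[ASEvent],
    junctions: JunctionTable,
    boundaries: Optional[BoundaryTable] = None,
    samples: Optional[Sequence[str]] = None,
) -> list[ASEQuant]:
    """Per-sample alt/model read counts for each event.

    Boundary ("B") support contributes the rounded mean of the intron's two
    boundary counts.  `samples` defaults to every sample seen in the
    junction and boundary tables.
    """
    boundaries = boundaries or {}
    if samples is None:
        seen: set[str] = set()
        for per in junctions.values():
            seen.update(per)
        for per in boundaries.values():
            seen.update(per)
        samples = sorted(seen)
    quants = []
    for ev in events:
        for sample in samples:
            alt = sum(_key_count(k, sample, junctions, boundaries) for k in ev.alt_support)
            model = sum(_key_count(k, sample, junctions, boundaries) for k in ev.model_support)
            quants.append(ASEQuant(ev.event_id, sample, alt, model))
    return quants


def filter_events(
    events: Sequence[ASEvent],
    quants: Sequence[ASEQuant],
    min_reads: int = 10,
    min_fraction: float = 0.8,
) -> list[ASEvent]:
    """Keep events with detectable junction support in every sample and
    >= `min_reads` total support in >= `min_fraction` of samples."""
    totals: dict[str, list[int]] = {}
    for q in quants:
        totals.setdefault(q.event_id, []).append(q.alt_reads + q.model_reads)
    kept = []
    for ev in events:
        ts = totals.get(ev.event_id, [])
        if not ts or min(ts) <= 0:
            continue
        if sum(t >= min_reads for t in ts) / len(ts) >= min_fraction:
            kept.append(ev)
    return kept


# ---------------------------------------------------------------------------
# differential tests
# ---------------------------------------------------------------------------


def test_rase_fisher(
    q1: ASEQuant,
    q2: ASEQuant,
    as_type: str = "",
    ratio_threshold: float = 0.2,
    alpha: float = 0.05,
) -> Optional[RASECall]:
    """Two-sided Fisher's exact test on [[alt1, model1], [alt2, model2]].

    q1 is the control sample, q2 the treatment.  Returns None (logged) when
    either sample has no reads, leaving the event untestable.
    """
    if q1.ratio is None or q2.ratio is None:
        logger.info("event %s untestable: a sample has no reads", q1.event_id)
        return None
    _, p = stats.fisher_exact(
        [[q1.alt_reads, q1.model_reads], [q2.alt_reads, q2.model_reads]],
        alternative="two-sided",
    )
    rr = abs(q1.ratio - q2.ratio)
    return RASECall(
        event_id=q1.event_id,
        as_type=as_type,
        rase_ratio=rr,
        pvalue=float(p),
        method="fisher",
        significant=bool(p <= alpha and rr >= ratio_threshold),
        direction="up" if q2.ratio > q1.ratio else "down",
    )


def test_rase_ttest(
    group1: Sequence[ASEQuant],
    group2: Sequence[ASEQuant],
    as_type: str = "",
    alpha: float = 0.05,
) -> RASECall:
    """Pooled-variance two-sample Student t-test on per-sample ratios.

    group1 is control, group2 treatment; each needs >= 2 defined ratios.
    Degenerate zero-variance cases: equal means give p = 1, unequal means
    give p = 0 (logged).
    """
    r1 = [q.ratio for q in group1 if q.ratio is not None]
    r2 = [q.ratio for q in group2 if q.ratio is not None]
    if len(r1) < 2 or len(r2) < 2:
        raise ValueError("t-test needs >= 2 defined ratios per group")
    m1, m2 = float(np.mean(r1)), float(np.mean(r2))
    if np.var(r1) == 0 and np.var(r2) == 0:
        if m1 == m2:
            p = 1.0
        else:
            logger.info("event %s: zero variance with unequal means, p -> 0", group1[0].event_id)
            p = 0.0
    else:
        _, p = stats.ttest_ind(r1, r2, equal_var=True)
        p = float(p)
    rr = abs(m1 - m2)
    return RASECall(
        event_id=group1[0].event_id,
        as_type=as_type,
        rase_ratio=rr,
        pvalue=p,
        method="ttest",
        significant=bool(p <= alpha),
        direction="up" if m2 > m1 else "down",
    )


def call_rases(
    events: Sequence[ASEvent],
    quants: Sequence[ASEQuant],
    ctrl_samples: Sequence[str],
    treat_samples: Sequence[str],
    ratio_threshold: float = 0.2,
    alpha: float = 0.05,
    apply_bh: bool = False,
) -> list[RASECall]:
    """Test every event: Fisher for a 1 vs 1 comparison, Student's t
    otherwise.  `apply_bh` optionally re-derives significance from
    Benjamini-Hochberg adjusted p-values (off by default: the threshold
    policy uses raw p)."""
    by_event: dict[str, dict[str, ASEQuant]] = {}
    for q in quants:
        by_event.setdefault(q.event_id, {})[q.sample_id] = q
    calls: list[RASECall] = []
    for ev in events:
        qs = by_event.get(ev.event_id, {})
        g1 = [qs[s] for s in ctrl_samples if s in qs]
        g2 = [qs[s] for s in treat_samples if s in qs]
        if len(ctrl_samples) == 1 and len(treat_samples) == 1:
            if not g1 or not g2:
                continue
            call = test_rase_fisher(
                g1[0], g2[0], ev.as_type, ratio_threshold=ratio_threshold, alpha=alpha
            )
            if call is not None:
                calls.append(call)
        else:
            try:
                calls.append(test_rase_ttest(g1, g2, ev.as_type, alpha=alpha))
            except ValueError:
                logger.info("event %s untestable: too few defined ratios", ev.event_id)
    if apply_bh and calls:
        from .expression import bh_fdr

        adj = bh_fdr([c.pvalue for c in calls])
        calls = [
            RASECall(
                c.event_id,
                c.as_type,
                c.rase_ratio,
                c.pvalue,
                c.method,
                bool(
                    a <= alpha
                    and (c.method != "fisher" or c.rase_ratio >= ratio_threshold)
                ),
                c.direction,
            )
            for c, a in zip(calls, adj)
        ]
    return calls


def summarize_rase(calls: Sequence[RASECall]) -> pd.DataFrame:
    """Up/down counts of significant calls per AS type."""
    sig = [c for c in calls if c.significant]
    if not sig:
        return pd.DataFrame(columns=["up", "down"]).rename_axis("as_type")
    df = pd.DataFrame({"as_type": [c.as_type for c in sig], "direction": [c.direction for c in sig]})
    out = (
        df.groupby(["as_type", "direction"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
    )
    out.columns.name = None
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def events_to_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "gene_id": [e.gene_id for e in events],
            "as_type": [e.as_type for e in events],
            "chrom": [e.alt_region.chrom for e in events],
            "strand": [e.alt_region.strand for e in events],
            "alt_region_start": [e.alt_region.start for e in events],
            "alt_region_end": [e.alt_region.end for e in events],
            "alt_support": [";".join(f"{k[0]}:{k[3]}-{k[4]}" for k in e.alt_support) for e in events],
            "model_support": [";".join(f"{k[0]}:{k[3]}-{k[4]}" for k in e.model_support) for e in events],
        }
    )


def quants_to_frame(quants: Sequence[ASEQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [q.event_id for q in quants],
            "sample_id": [q.sample_id for q in quants],
            "alt_reads": [q.alt_reads for q in quants],
            "model_reads": [q.model_reads for q in quants],
            "ratio": [q.ratio for q in quants],
        }
    )


def calls_to_frame(calls: Sequence[RASECall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [c.event_id for c in calls],
            "as_type": [c.as_type for c in calls],
            "rase_ratio": [c.rase_ratio for c in calls],
            "pvalue": [c.pvalue for c in calls],
            "method": [c.method for c in calls],
            "significant": [c.significant for c in calls],
            "direction": [c.direction for c in calls],
        }
    )
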