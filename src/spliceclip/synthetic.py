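"""Synthetic annotation, reads and count tables with planted ground truth.

Every generator is deterministic under a fixed seed and emits a truth table
alongside its data, so each downstream stage (splicing calls, CLIP peaks,
differential expression) can be scored against known answers without any
external dataset.

Gene structures are built from a fixed five-exon backbone; for each of the
ten alternative-splicing types one template realises the type with a
transcript pair (or with unannotated junction evidence, for event types
that are by definition absent from the annotation).  Junction evidence is
simulated directly as spliced reads rather than by fragmenting full
transcripts, which is sufficient for every junction-based statistic in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import AlignedRead, GeneModel, GenomicInterval, Transcript

#: the ten supported alternative-splicing event types
AS_TYPES = (
    "ES",
    "A5SS",
    "A3SS",
    "IntronR",
    "MXE",
    "5pMXE",
    "3pMXE",
    "CassetteExon",
    "A3SS&ES",
    "A5SS&ES",
)

#: evidence-key kinds: junction reads ("J") or intron-boundary reads ("B")
JKEY, BKEY = "J", "B"


@dataclass(frozen=True)
class SpliceTruth:
    """Planted splicing event: true alt-read fractions per condition."""

    event_id: str
    gene_id: str
    as_type: str
    true_ratio_ctrl: float
    true_ratio_kd: float

    @property
    def differential(self) -> bool:
        return abs(self.true_ratio_kd - self.true_ratio_ctrl) > 0


@dataclass(frozen=True)
class PeakTruth:
    """Planted CLIP binding site: read density `enrichment`-fold over background."""

    gene_id: str
    interval: GenomicInterval
    enrichment: float

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("planted peak enrichment must exceed 1")


@dataclass(frozen=True)
class DEGTruth:
    """Planted expression change for one gene."""

    gene_id: str
    log2fc: float
    baseline_mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")


@dataclass(frozen=True)
class EventBlueprint:
    """The evidence structure of the single event a synthetic gene hosts.

    Keys are global evidence keys: ("J", chrom, strand, start, end) for a
    splice junction, ("B", chrom, strand, start, end) for the exon-intron
    boundaries of a retained intron.
    """

    gene_id: str
    as_type: str
    chrom: str
    strand: str
    alt_keys: tuple[tuple, ...]
    model_keys: tuple[tuple, ...]
    alt_region: GenomicInterval


# ---------------------------------------------------------------------------
# gene-structure templates (local coordinates, plus-strand orientation)
# ---------------------------------------------------------------------------

_E = [(0, 200), (500, 700), (1000, 1200), (1500, 1700), (2000, 2200)]
_SPAN = 2200
_CDS_DEFAULT = (100, 2100)


def _template(as_type: str):
    """Transcript structures + local blueprint for one AS type.

    Returns (transcripts, alt_keys, model_keys, alt_region) where
    transcripts is a list of (exon list, cds span) and keys are local
    ("J"|"B", start, end) tuples.
    """
    E = _E
    if as_type == "ES":
        return (
            [(E, _CDS_DEFAULT), ([E[0], E[1], E[3], E[4]], _CDS_DEFAULT)],
            [(JKEY, 700, 1500)],
            [(JKEY, 700, 1000), (JKEY, 1200, 1500)],
            (1000, 1200),
        )
    if as_type == "CassetteExon":
        # the cassette exon is absent from the annotation; inclusion
        # junctions are novel, the spanning junction is annotated
        return (
            [([E[0], E[1], E[3], E[4]], _CDS_DEFAULT)],
            [(JKEY, 700, 1000), (JKEY, 1200, 1500)],
            [(JKEY, 700, 1500)],
            (1000, 1200),
        )
    if as_type == "A5SS":
        return (
            [(E, _CDS_DEFAULT), ([E[0], (500, 750), E[2], E[3], E[4]], _CDS_DEFAULT)],
            [(JKEY, 750, 1000)],
            [(JKEY, 700, 1000)],
            (700, 750),
        )
    if as_type == "A3SS":
        return (
            [(E, _CDS_DEFAULT), ([E[0], E[1], (950, 1200), E[3], E[4]], _CDS_DEFAULT)],
            [(JKEY, 700, 950)],
            [(JKEY, 700, 1000)],
            (950, 1000),
        )
    if as_type == "IntronR":
        return (
            [(E, _CDS_DEFAULT)],
            [(BKEY, 700, 1000)],
            [(JKEY, 700, 1000)],
            (700, 1000),
        )
    if as_type == "MXE":
        return (
            [([E[0], E[1], E[2], E[4]], _CDS_DEFAULT), ([E[0], E[1], E[3], E[4]], _CDS_DEFAULT)],
            [(JKEY, 700, 1500), (JKEY, 1700, 2000)],
            [(JKEY, 700, 1000), (JKEY, 1200, 2000)],
            (1500, 1700),
        )
    if as_type == "5pMXE":
        cds = (1550, 2100)
        return (
            [([E[0], E[1], E[3], E[4]], cds), ([E[0], E[2], E[3], E[4]], cds)],
            [(JKEY, 200, 1000), (JKEY, 1200, 1500)],
            [(JKEY, 200, 500), (JKEY, 700, 1500)],
            (1000, 1200),
        )
    if as_type == "3pMXE":
        cds = (100, 650)
        return (
            [([E[0], E[1], E[2], E[4]], cds), ([E[0], E[1], E[3], E[4]], cds)],
            [(JKEY, 700, 1500), (JKEY, 1700, 2000)],
            [(JKEY, 700, 1000), (JKEY, 1200, 2000)],
            (1500, 1700),
        )
    if as_type == "A3SS&ES":
        # novel junction from an annotated donor to an acceptor inside the
        # downstream exon, skipping the annotated exon in between
        return (
            [(E, _CDS_DEFAULT)],
            [(JKEY, 700, 1550)],
            [(JKEY, 700, 1000), (JKEY, 1200, 1500)],
            (700, 1550),
        )
    if as_type == "A5SS&ES":
        return (
            [(E, _CDS_DEFAULT)],
            [(JKEY, 650, 1500)],
            [(JKEY, 700, 1000), (JKEY, 1200, 1500)],
            (650, 1500),
        )
    raise ValueError(f"unknown AS type {as_type!r}")


def _reflect(x: int) -> int:
    return _SPAN - x


def _reflect_pair(s: int, e: int) -> tuple[int, int]:
    return _reflect(e), _reflect(s)


def make_gene_models(
    n_genes: int, seed: int, chrom: str = "chr1", gap: int = 3000
) -> tuple[list[GeneModel], dict[str, EventBlueprint]]:
    """Build `n_genes` synthetic gene models covering all ten AS types.

    Types are assigned cyclically, strands alternate, and intergenic gaps
    vary with the seed.  Every gene has a CDS and both UTRs and hosts at
    most one planted splicing event, keeping truth attribution unambiguous.
    Raises if `n_genes` is too small to host all ten types.
    """
    if n_genes < len(AS_TYPES):
        raise ValueError(f"need >= {len(AS_TYPES)} genes to host all AS types")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    blueprints: dict[str, EventBlueprint] = {}
    offset = 1000
    for i in range(n_genes):
        as_type = AS_TYPES[i % len(AS_TYPES)]
        # shift strand parity each full type cycle so every type appears on
        # both strands once n_genes >= 2 * len(AS_TYPES)
        strand = "+" if (i + i // len(AS_TYPES)) % 2 == 0 else "-"
        gene_id = f"G{i + 1:04d}"
        txs, alt_keys, model_keys, region = _template(as_type)

        def fix_keys(keys):
            out = []
            for kind, s, e in keys:
                if strand == "-":
                    s, e = _reflect_pair(s, e)
                out.append((kind, chrom, strand, s + offset, e + offset))
            return tuple(sorted(out))

        transcripts = []
        for j, (exons, cds) in enumerate(txs):
            if strand == "-":
                exons = sorted(_reflect_pair(s, e) for s, e in exons)
                cds = _reflect_pair(*cds)
            ivs = tuple(
                GenomicInterval(chrom, s + offset, e + offset, strand) for s, e in exons
            )
            cds_iv = GenomicInterval(chrom, cds[0] + offset, cds[1] + offset, strand)
            transcripts.append(Transcript(f"{gene_id}.t{j + 1}", gene_id, ivs, cds_iv))
        rs, re_ = region if strand == "+" else _reflect_pair(*region)
        blueprints[gene_id] = EventBlueprint(
            gene_id=gene_id,
            as_type=as_type,
            chrom=chrom,
            strand=strand,
            alt_keys=fix_keys(alt_keys),
            model_keys=fix_keys(model_keys),
            alt_region=GenomicInterval(chrom, rs + offset, re_ + offset, strand),
        )
        genes.append(GeneModel(gene_id, tuple(transcripts)))
        offset += _SPAN + gap + int(rng.integers(0, 1000))
    return genes, blueprints


def make_splice_truths(
    blueprints: dict[str, EventBlueprint],
    frac_differential: float = 0.5,
    ratio_ctrl: float = 0.9,
    ratio_kd: float = 0.3,
    null_ratio: float = 0.5,
    seed: int = 0,
) -> list[SpliceTruth]:
    """Assign true alt-read fractions: a `frac_differential` subset changes
    between conditions (ctrl 0.9 -> kd 0.3 by default), the rest stay at
    `null_ratio` in both."""
    rng = np.random.default_rng(seed)
    truths = []
    for gene_id in sorted(blueprints):
        bp = blueprints[gene_id]
        diff = bool(rng.random() < frac_differential)
        truths.append(
            SpliceTruth(
                event_id=f"{gene_id}:{bp.as_type}",
                gene_id=gene_id,
                as_type=bp.as_type,
                true_ratio_ctrl=ratio_ctrl if diff else null_ratio,
                true_ratio_kd=ratio_kd if diff else null_ratio,
            )
        )
    return truths


def splice_truth_frame(truths: Sequence[SpliceTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [t.event_id for t in truths],
            "gene_id": [t.gene_id for t in truths],
            "as_type": [t.as_type for t in truths],
            "true_ratio_ctrl": [t.true_ratio_ctrl for t in truths],
            "true_ratio_kd": [t.true_ratio_kd for t in truths],
            "differential": [t.differential for t in truths],
        }
    )


def simulate_rnaseq(
    genes: Sequence[GeneModel],
    blueprints: dict[str, EventBlueprint],
    truths: Sequence[SpliceTruth],
    depth: float = 200.0,
    n_reps: int = 2,
    seed: int = 0,
    flank: int = 50,
) -> dict[str, list[AlignedRead]]:
    """Simulate junction/boundary evidence reads for planted splicing events.

    Per event and sample, the total evidence count is Poisson(`depth`) and
    the alternative fraction is binomial with the condition's true ratio.
    Junction molecules become two-block spliced reads (`flank` bases each
    side); intron-retention molecules become single-block reads spanning
    both exon-intron boundaries of the retained intron.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [f"ctrl_{i + 1}" for i in range(n_reps)] + [
        f"kd_{i + 1}" for i in range(n_reps)
    ]
    reads: dict[str, list[AlignedRead]] = {s: [] for s in samples}
    counter = 0

    def emit_junction(sample: str, key: tuple, count: int) -> None:
        nonlocal counter
        _, chrom, strand, s, e = key
        for _ in range(count):
            counter += 1
            blocks = (
                GenomicInterval(chrom, s - flank, s, strand),
                GenomicInterval(chrom, e, e + flank, strand),
            )
            reads[sample].append(AlignedRead(f"r{counter}", sample, chrom, strand, blocks))

    def emit_boundary(sample: str, key: tuple, count: int) -> None:
        # a retained-intron molecule spans both boundaries: one read at each
        nonlocal counter
        _, chrom, strand, s, e = key
        half = max(1, flank // 2)
        for pos in (s, e):
            for _ in range(count):
                counter += 1
                block = (GenomicInterval(chrom, pos - half, pos + half, strand),)
                reads[sample].append(AlignedRead(f"r{counter}", sample, chrom, strand, block))

    for truth in sorted(truths, key=lambda t: t.gene_id):
        bp = blueprints[truth.gene_id]
        for sample in samples:
            ratio = truth.true_ratio_ctrl if sample.startswith("ctrl") else truth.true_ratio_kd
            total = int(rng.poisson(depth))
            alt_n = int(rng.binomial(total, ratio)) if total else 0
            model_n = total - alt_n
            for keys, n in ((bp.alt_keys, alt_n), (bp.model_keys, model_n)):
                jkeys = [k for k in keys if k[0] == JKEY]
                bkeys = [k for k in keys if k[0] == BKEY]
                if bkeys:
                    # retention evidence goes to the boundary keys
                    for k in bkeys:
                        emit_boundary(sample, k, n)
                elif jkeys:
                    split = rng.multinomial(n, [1 / len(jkeys)] * len(jkeys))
                    for k, c in zip(jkeys, split):
                        emit_junction(sample, k, int(c))
    return reads


# ---------------------------------------------------------------------------
# CLIP
# ---------------------------------------------------------------------------


def make_peak_truths(
    genes: Sequence[GeneModel],
    frac_with_peak: float = 0.5,
    enrichment: float = 20.0,
    peak_len: int = 60,
    read_len: int = 30,
    seed: int = 0,
) -> list[PeakTruth]:
    """Plant one binding site in a random subset of genes."""
    rng = np.random.default_rng(seed)
    truths = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if rng.random() >= frac_with_peak:
            continue
        sp = g.span
        lo, hi = sp.start + read_len, sp.end - read_len - peak_len
        start = int(rng.integers(lo, hi))
        truths.append(
            PeakTruth(
                gene_id=g.gene_id,
                interval=GenomicInterval(sp.chrom, start, start + peak_len, sp.strand),
                enrichment=enrichment,
            )
        )
    return truths


def simulate_clip(
    genes: Sequence[GeneModel],
    peaks: Sequence[PeakTruth],
    background_per_kb: float = 10.0,
    read_len: int = 30,
    seed: int = 0,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Simulate an IP and a matched input CLIP sample.

    Both samples carry uniform background over every gene span at
    `background_per_kb`; the IP sample additionally carries reads
    concentrated in each planted interval at enrichment x background
    density.  Returns (ip_reads, input_reads).
    """
    rng = np.random.default_rng(seed)
    by_gene = {p.gene_id: p for p in peaks}
    gene_ids = {g.gene_id for g in genes}
    for p in peaks:
        if p.gene_id not in gene_ids:
            raise ValueError(f"peak truth references unknown gene {p.gene_id}")
    ip: list[AlignedRead] = []
    inp: list[AlignedRead] = []
    counter = 0

    def place(out: list[AlignedRead], sample: str, g: GeneModel, n: int, lo: int, hi: int) -> None:
        nonlocal counter
        if n <= 0 or hi < lo:
            return
        starts = rng.integers(lo, hi + 1, size=n)
        for s in np.sort(starts):
            counter += 1
            block = (GenomicInterval(g.chrom, int(s), int(s) + read_len, g.strand),)
            out.append(AlignedRead(f"c{counter}", sample, g.chrom, g.strand, block))

    for g in sorted(genes, key=lambda g: g.gene_id):
        sp = g.span
        if read_len > sp.length:
            raise ValueError(f"read length {read_len} exceeds span of {g.gene_id}")
        lam = background_per_kb * sp.length / 1000.0
        place(inp, "input", g, int(rng.poisson(lam)), sp.start, sp.end - read_len)
        place(ip, "ip", g, int(rng.poisson(lam)), sp.start, sp.end - read_len)
        p = by_gene.get(g.gene_id)
        if p is not None:
            if not sp.contains(p.interval):
                raise ValueError(f"planted interval outside span of {g.gene_id}")
            n_extra = int(rng.poisson(p.enrichment * background_per_kb * p.interval.length / 1000.0))
            lo = max(sp.start, p.interval.start)
            hi = min(sp.end - read_len, p.interval.end - read_len)
            if hi < lo:  # peak shorter than a read: centre reads on it
                lo = max(sp.start, p.interval.end - read_len)
                hi = min(sp.end - read_len, p.interval.start)
            place(ip, "ip", g, n_extra, lo, hi)
    return ip, inp


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def make_deg_truths(
    n_genes: int,
    frac_de: float = 0.1,
    lfc: float = 3.0,
    baseline_mean: float = 300.0,
    baseline_sigma: float = 0.8,
    dispersion: float = 0.05,
    seed: int = 0,
) -> list[DEGTruth]:
    """Planted fold changes: a `frac_de` subset at +/-`lfc` (signs balanced)."""
    rng = np.random.default_rng(seed)
    truths = []
    sign = 1.0
    for i in range(n_genes):
        de = rng.random() < frac_de
        this_lfc = 0.0
        if de:
            this_lfc = sign * lfc
            sign = -sign
        base = float(baseline_mean * rng.lognormal(0.0, baseline_sigma))
        truths.append(DEGTruth(f"G{i + 1:05d}", this_lfc, base, dispersion))
    return truths


def simulate_counts(
    degs: Sequence[DEGTruth],
    n_reps: int = 2,
    library_size: Optional[float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count matrix (genes x samples) with planted fold
    changes applied in the kd condition.

    Variance follows mu + dispersion * mu^2; dispersion ~ 0 degenerates to
    Poisson.  Baseline means are rescaled so the expected control column
    total equals `library_size` (when given).
    """
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed)
    base = np.array([d.baseline_mean for d in degs], dtype=float)
    lfc = np.array([d.log2fc for d in degs], dtype=float)
    disp = np.array([d.dispersion for d in degs], dtype=float)
    if library_size is not None:
        base = base * (library_size / base.sum())
    mu = {"ctrl": base, "kd": base * np.power(2.0, lfc)}
    cols = {}
    for cond in ("ctrl", "kd"):
        for rep in range(1, n_reps + 1):
            m = mu[cond]
            counts = np.empty(len(m), dtype=np.int64)
            poisson_like = disp < 1e-8
            counts[poisson_like] = rng.poisson(m[poisson_like])
            nb = ~poisson_like
            if nb.any():
                size = 1.0 / disp[nb]
                p = size / (size + m[nb])
                counts[nb] = rng.negative_binomial(size, p)
            cols[f"{cond}_{rep}"] = counts
    return pd.DataFrame(cols, index=[d.gene_id for d in degs])


def deg_truth_frame(degs: Sequence[DEGTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [d.gene_id for d in degs],
            "log2fc": [d.log2fc for d in degs],
            "baseline_mean": [d.baseline_mean for d in degs],
            "dispersion": [d.dispersion for d in degs],
        }
    )
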