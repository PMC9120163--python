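# Methods

## Coordinates and overlap

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
is converted at the I/O boundary.  "Overlap" always means ≥ 1 shared
base under half-open arithmetic, so `[0,10)` and `[10,20)` do not
overlap.  SAM records flagged secondary or supplementary are excluded
so only uniquely-placed alignments contribute; BED12 input is assumed
pre-filtered.  Deletions (CIGAR `D`) stay inside a block; only `N` gaps
define splice junctions.

When a position falls in several genes, the strand-matching gene with
the smallest span is used, and region precedence within a gene is
cds > 5utr > 3utr > intron.  This tie-break is a package convention —
real multi-gene loci are genuinely ambiguous — and it is applied
identically in read classification, peak assignment and metagene
profiling so the outputs are mutually consistent.  Exonic bases of a
transcript without an annotated CDS are counted as CDS.

## Splicing event construction

The ten event types are built from the observed junction table against
the annotation (annotated introns, exon boundary sets, UTR unions):

* **A5SS / A3SS** — two junctions sharing one genomic end with no
  annotated exon in the differing region; naming is strand-aware (the
  donor is the intron's 5′ end in transcription direction).  The
  annotated junction is the model; when both are annotated the one from
  the lowest-indexed transcript wins (deterministic).
* **ES** — a junction joining two annotated boundaries with ≥ 1
  annotated exon fully inside and the annotated inclusion introns
  present; alt = skipping junction, model = inclusion junctions.
* **CassetteExon** — two novel junctions from an annotated intron's
  donor into, and out of, an internal interval; alt = inclusion pair,
  model = the annotated spanning junction.  Treated as the
  direction-opposite of ES.
* **IntronR** — alt = reads spanning the intron's two exon–intron
  boundaries (≥ 1 base each side; the two boundary counts are
  averaged), model = the intron's junction reads.  Higher retention in
  the treatment group is reported as direction "up".
* **MXE / 5pMXE / 3pMXE** — two disjoint exon paths between common
  flanks, with no junction linking the two exons and no direct
  flank-to-flank junction; the UTR-specific labels apply when both
  alternative exons lie inside the gene's 5′/3′ UTR union.
* **A3SS&ES / A5SS&ES** — a junction with one annotated and one novel
  end that skips ≥ 1 annotated exon; model = the annotated introns
  inside its span.

Detection passes run cassette → MXE → skipping/combined → splice-site
pairs → intron retention, consuming junctions as they are explained, so
one junction supports one event.  Junctions consistent with more than
one gene (span containment, matching strand) are assigned to none.

Whether the original event-level pipelines required annotation support
for both junctions of a splice-site pair is not publicly specified; we
require at least one annotated junction and treat it as the model.

## Splicing statistics

Per-sample splicing ratio r = alt/(alt+model), undefined when both are
zero (the event is then untestable for that comparison and logged).
The RASE ratio |r̄₁ − r̄₂| lies in [0,1], which makes the 0.2 threshold
meaningful.  Pairwise designs use the two-sided Fisher exact test
(probability mass ≤ observed-table mass); significance requires
p ≤ 0.05 and RASE ratio ≥ 0.2.  Replicated designs use the
pooled-variance Student t-test on per-sample ratios at p ≤ 0.05 (no
ratio threshold, matching the threshold policy for replicated
comparisons).  Zero-variance degenerate cases: equal means → p = 1,
unequal means → p = 0 (logged).  Raw p-values are used by default; a
Benjamini–Hochberg option exists but is off, matching the original
policy.  The event filter requires support > 0 in every sample and
≥ 10 reads in ≥ 80 % of samples.

## CLIP peak calling

Reads sharing ≥ 1 base (per chrom/strand) are clustered transitively;
the peak interval is the cluster extent and the height is the maximum
per-base depth of the read spans.  The per-gene null re-places the
gene's peak reads — because every read belongs to a cluster, this is
the gene's read set — uniformly at random with their original lengths
fully inside the gene span (introns included; exon-union placement is
available via `placement="exonic"`), re-clusters, and records the
maximum height; 500 iterations by default.  Span placement mirrors the
intron-heavy distribution of real CLIP input libraries.  The empirical
p uses the add-one estimator (1 + #{null ≥ h})/(n_iter + 1), so p ∈
(0,1] and is never exactly zero; peaks with p < 0.05 are kept.  IP
peaks sharing ≥ 1 base (same chrom and strand) with any input peak are
removed; the operation is idempotent.  Peaks are assigned to the
strand-matching gene containing their midpoint (smallest span wins).
Replicate support is defined at peak level: peaks from two IP samples
merge when they share ≥ 1 base.

Metagene profiles rescale each gene's 5′UTR/CDS/3′UTR exonic regions to
100 bins; a read midpoint at exonic offset o of a region of length L
lands in bin ⌊o·100/L⌋ (ties to the lower bin, capped at 99), mirrored
for minus-strand genes.  K-mer enrichment is a transparent
sequence-composition summary (fold with pseudocount 1 per k-mer in both
sets, binomial z-score), not a de-novo motif finder with position
weight matrices.

## Expression

FPKM = counts·10⁹/(exon-union length × total mapped).  Differential
expression is a threshold policy — fold change ≥ 2 (|log2FC| ≥ 1 on
total-count-normalized means with pseudocount 1) and BH-FDR ≤ 0.05 —
over a pluggable per-gene test.  The default test is a pooled-variance
t-test on log2 normalized counts: a deliberately simple, documented
choice; any callable producing per-gene p-values (e.g. a
negative-binomial exact test) can be slotted in.  Normalization is
total-count; trimmed-mean methods are out of scope.  ΔΔCt follows
2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference) and group-mean
differences; swapping groups inverts the relative quantity exactly.
Sample correlation uses Pearson r on log2(FPKM+1) and average-linkage
clustering on 1 − r with deterministic leaf order; constant columns are
reported missing and ordered last.

## Integration

Overlap significance is the accumulative (upper-tail) hypergeometric
probability, computed via the survival function (log-space stable).
The recommended universe for bound-gene × splicing-gene tests is the
set of genes detectably expressed in the RNA-seq; in the synthetic
pipeline it is the simulated gene set.  Term enrichment keeps terms
with p < 0.01, count ≥ 3 and enrichment factor > 1.5 (observed/expected
with expected = |list|·|term|/N), with BH q-values computed across all
tested terms before filtering.  Term tables are user-supplied;
no ontology database is bundled.

## Synthetic data: what it emulates and what it does not

Gene structures come from a fixed five-exon backbone (200-bp exons,
300-bp introns, span 2.2 kb) with one template per event type; minus
-strand genes are mirror images, so both strands are exercised.  Event
types that are by definition absent from the annotation (cassette exon,
A3SS&ES, A5SS&ES) annotate only the reference isoform and plant novel
junction evidence.  Each gene hosts at most one event, keeping truth
attribution unambiguous.

Junction evidence is simulated directly: per event and sample the total
evidence count is Poisson(depth) and the alternative count binomial
with the condition's true ratio; junction molecules become two-block
spliced reads (50 bp each side) and retained-intron molecules become
boundary-spanning reads at both boundaries.  This is sufficient for
every junction-based statistic but does not model exon-body coverage,
fragment-length distributions, sequencing error or positional bias —
passing tests demonstrate the statistics and constructions, not
robustness to alignment artefacts.  CLIP simulation places uniform
background (default 10 reads/kb, 30-bp reads) over gene spans plus
reads at enrichment × background density inside planted 60-bp
intervals (default enrichment 20).  Counts are negative-binomial with
variance μ + φμ² (φ → 0 recovers Poisson), planted |log2FC| = 3 with
balanced signs in 10 % of genes.

Default study conditions: splicing true ratios 0.9 (control) vs 0.3
(knockdown) at depth 200 with 2 replicates per condition;
differential-expression measurements use baseline mean 500 (lognormal
spread 0.5), dispersion 0.05 and 3 replicates per condition — the
conditions under which the threshold policy is expected to recover
≥ 95 % of planted changes.  All generators are deterministic under a
fixed seed, and truth tables are emitted alongside the data.

## Numerical and reproducibility notes

* Empirical p-values can never be zero (add-one estimator); Fisher and
  hypergeometric p-values come from exact routines and are checked
  against rational-arithmetic enumeration oracles in the tests.
* BH adjustment is the standard step-up procedure.  It is monotone on
  sorted inputs but *not* idempotent on its own output (re-adjusting
  multiplies by n/rank again); callers should adjust raw p-values once.
* The pipeline derives all stage seeds from one user seed; per-gene
  null seeds are stable hashes of gene ids so results do not depend on
  iteration order.  Problem sizes in the acceptance script (200 genes
  for recovery, 1000 null events, 2000 count genes) were chosen as the
  smallest sizes at which the measured rates are stable to ~1 %.
* Known limitations: no novel-junction discovery from unaligned reads,
  no isoform-level quantification, no crosslink-site analysis, no
  model-based (negative-binomial) peak calling; multi-gene loci use the
  documented smallest-span tie-break.
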