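"""End-to-end run on synthetic data with truth-vs-called recovery scoring.

Generates annotation, RNA-seq junction evidence, CLIP IP/input reads and
a count matrix with planted truth, runs every analysis stage, and reports
sensitivity / false-discovery metrics against the planted truth as a
plain dict (JSON-serialisable).  Identical seeds give identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import clip as clipmod
from . import expression as exprmod
from . import integration as integmod
from . import splicing as splmod
from . import synthetic as synmod


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 1
    n_genes: int = 40
    depth: float = 200.0
    n_reps: int = 2
    ratio_threshold: float = 0.2
    pvalue_threshold: float = 0.05
    min_reads: int = 10
    min_fraction: float = 0.8
    background_per_kb: float = 10.0
    clip_enrichment: float = 20.0
    clip_frac_with_peak: float = 0.5
    iterations: int = 500
    alpha: float = 0.05
    placement: str = "span"
    n_count_genes: int = 500
    frac_de: float = 0.1
    deg_lfc: float = 3.0
    deg_n_reps: int = 3
    deg_baseline: float = 500.0
    deg_baseline_sigma: float = 0.5
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("ratio_threshold", 0, 1),
            ("pvalue_threshold", 0, 1),
            ("alpha", 0, 1),
            ("min_fraction", 0, 1),
            ("fdr_threshold", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= 1):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.iterations < 100:
            raise ValueError("iterations must be >= 100")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data and score against planted truth."""
    seed = config.seed
    result: dict = {"config": asdict(config), "config_hash": config.config_hash()}

    # --- splicing stage -----------------------------------------------------
    genes, blueprints = synmod.make_gene_models(config.n_genes, seed=seed)
    truths = synmod.make_splice_truths(blueprints, seed=seed + 1)
    reads = synmod.simulate_rnaseq(
        genes, blueprints, truths, depth=config.depth, n_reps=config.n_reps, seed=seed + 2
    )
    all_reads = [r for rs in reads.values() for r in rs]
    junctions = splmod.extract_junctions(all_reads)
    boundaries = splmod.extract_boundary_counts(all_reads, genes)
    events = splmod.detect_as_events(genes, junctions, boundaries)
    samples = sorted(reads)
    quants = splmod.quantify_events(events, junctions, boundaries, samples)
    events = splmod.filter_events(
        events, quants, min_reads=config.min_reads, min_fraction=config.min_fraction
    )
    quants = [q for q in quants if q.event_id in {e.event_id for e in events}]
    ctrl = [s for s in samples if s.startswith("ctrl")]
    kd = [s for s in samples if s.startswith("kd")]
    calls = splmod.call_rases(
        events,
        quants,
        ctrl,
        kd,
        ratio_threshold=config.ratio_threshold,
        alpha=config.pvalue_threshold,
    )
    planted = {
        (t.gene_id, t.as_type): t.differential for t in truths
    }
    event_by_id = {e.event_id: e for e in events}
    sig_keys = set()
    called_keys = set()
    for c in calls:
        ev = event_by_id[c.event_id]
        bp = blueprints.get(ev.gene_id)
        if bp is not None and set(ev.alt_support) == set(bp.alt_keys):
            called_keys.add((ev.gene_id, ev.as_type))
            if c.significant:
                sig_keys.add((ev.gene_id, ev.as_type))
    diff_truth = {k for k, d in planted.items() if d}
    null_truth = {k for k, d in planted.items() if not d}
    rasg = {gid for (gid, _t) in sig_keys}
    result["splicing"] = {
        "n_planted": len(planted),
        "n_detected": len(called_keys & set(planted)),
        "n_significant": len(sig_keys),
        "sensitivity": _frac(len(sig_keys & diff_truth), len(diff_truth & called_keys)),
        "detection_rate": _frac(len(called_keys & set(planted)), len(planted)),
        "null_call_rate": _frac(len(sig_keys & null_truth), len(null_truth & called_keys)),
        "per_type_counts": splmod.summarize_rase(calls).to_dict(),
    }

    # --- CLIP stage ---------------------------------------------------------
    peak_truths = synmod.make_peak_truths(
        genes,
        frac_with_peak=config.clip_frac_with_peak,
        enrichment=config.clip_enrichment,
        seed=seed + 3,
    )
    ip_reads, input_reads = synmod.simulate_clip(
        genes, peak_truths, background_per_kb=config.background_per_kb, seed=seed + 4
    )
    ip_kept, input_kept = [], []
    for sample_reads, kept in ((ip_reads, ip_kept), (input_reads, input_kept)):
        by_gene: dict[str, list] = {}
        gene_by_id = {g.gene_id: g for g in genes}
        idx = clipmod.GeneIndex(genes)
        for r in sample_reads:
            hits = idx.containing_point(r.chrom, r.span.midpoint, r.strand)
            if hits:
                g = min(hits, key=lambda g: (g.span.length, g.gene_id))
                by_gene.setdefault(g.gene_id, []).append(r)
        for gid in sorted(by_gene):
            g = gene_by_id[gid]
            peaks = clipmod.cluster_peaks(by_gene[gid])
            # every read belongs to a cluster, so the peak-read set is the
            # gene's read set
            lengths = [r.span.length for r in by_gene[gid]]
            null = clipmod.simulate_null(
                g,
                lengths,
                n_iter=config.iterations,
                seed=seed + 5 + _stable_gene_seed(gid),
                placement=config.placement,
            )
            kept.extend(clipmod.call_peaks(peaks, null, alpha=config.alpha))
    final_peaks = clipmod.subtract_input(ip_kept, input_kept)
    final_peaks, bound_genes = clipmod.assign_targets(final_peaks, genes)
    truth_by_gene = {p.gene_id: p for p in peak_truths}
    recovered = {
        p.gene_id
        for p in final_peaks
        if p.gene_id in truth_by_gene and p.interval.overlaps(truth_by_gene[p.gene_id].interval)
    }
    result["clip"] = {
        "n_planted": len(peak_truths),
        "n_final_peaks": len(final_peaks),
        "recovery": _frac(len(recovered), len(peak_truths)),
        "n_bound_genes": len(bound_genes),
    }

    # --- expression stage ---------------------------------------------------
    deg_truths = synmod.make_deg_truths(
        config.n_count_genes,
        frac_de=config.frac_de,
        lfc=config.deg_lfc,
        baseline_mean=config.deg_baseline,
        baseline_sigma=config.deg_baseline_sigma,
        seed=seed + 6,
    )
    counts = synmod.simulate_counts(deg_truths, n_reps=config.deg_n_reps, seed=seed + 7)
    design = {c: ("ctrl" if c.startswith("ctrl") else "kd") for c in counts.columns}
    degs = exprmod.call_degs(
        counts,
        design,
        fc_threshold=config.fc_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    de_truth = {d.gene_id for d in deg_truths if d.log2fc != 0}
    called_de = set(degs.index[degs["status"] != "unchanged"])
    null_genes = {d.gene_id for d in deg_truths if d.log2fc == 0}
    result["expression"] = {
        "n_planted_de": len(de_truth),
        "n_called_de": len(called_de),
        "n_up": int((degs["status"] == "up").sum()),
        "n_down": int((degs["status"] == "down").sum()),
        "sensitivity": _frac(len(called_de & de_truth), len(de_truth)),
        "null_call_rate": _frac(len(called_de & null_genes), len(null_genes)),
    }

    # --- integration stage --------------------------------------------------
    universe = {g.gene_id for g in genes}
    ov = integmod.overlap_test(bound_genes, rasg, universe)
    a_only, inter, b_only = integmod.venn_counts(bound_genes & universe, rasg & universe)
    result["integration"] = {
        "bound_only": a_only,
        "overlap": inter,
        "rasg_only": b_only,
        "hypergeom_pvalue": ov.pvalue,
    }
    return result


def _frac(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def _stable_gene_seed(gene_id: str) -> int:
    return int(hashlib.sha256(gene_id.encode()).hexdigest()[:6], 16)


def write_result(result: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
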