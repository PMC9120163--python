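"""Expression layers: FPKM, the fold-change + FDR threshold policy for
differential expression, qPCR ddCt quantification and sample correlation.

The differential-expression layer is a threshold policy over a pluggable
per-gene test: any callable mapping (ctrl matrix, treat matrix) on log2
normalized counts to per-gene p-values can be supplied.  The default is a
pooled-variance two-sample t-test on log2 total-count-normalized counts
(pseudocount 1), a deliberately simple stand-in for a negative-binomial
exact test; the thresholds (fold change >= 2 or <= 0.5, BH-FDR <= 0.05)
are what the policy is about.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference-gene cycle thresholds."""

    sample_id: str
    group: str
    ct_target: float
    ct_ref: float

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_ref <= 0:
            raise ValueError("Ct values must be positive")


def compute_fpkm(counts, gene_length_bp, total_mapped):
    """FPKM = counts * 1e9 / (gene length * total mapped fragments).

    Gene length is the length of the union of the gene's exons; accepts
    scalars or aligned arrays.
    """
    counts = np.asarray(counts, dtype=float)
    gene_length_bp = np.asarray(gene_length_bp, dtype=float)
    if np.any(gene_length_bp <= 0):
        raise ValueError("gene length must be positive")
    if not np.all(np.asarray(total_mapped) > 0):
        raise ValueError("total mapped fragments must be positive")
    out = counts * 1e9 / (gene_length_bp * total_mapped)
    return out if out.ndim else float(out)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def default_test(ctrl: np.ndarray, treat: np.ndarray) -> np.ndarray:
    """Per-gene pooled-variance t-test on log2 normalized counts.

    Genes with zero variance in both groups get p = 1 when the means are
    equal and p ~ 0 otherwise.
    """
    t, p = stats.ttest_ind(ctrl, treat, axis=1, equal_var=True)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(ctrl.mean(axis=1), treat.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def call_degs(
    counts: pd.DataFrame,
    design: dict[str, str] | pd.Series,
    ctrl: str = "ctrl",
    treat: str = "kd",
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    test: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
) -> pd.DataFrame:
    """Differential-expression calls under the fold-change + FDR policy.

    counts: genes x samples; design maps sample -> condition label.
    Counts are normalized to equal library size (total-count), log2fc uses
    mean normalized counts with pseudocount 1, p-values come from the
    pluggable test and are BH-adjusted across all genes.  status is "up"
    when log2fc >= log2(fc_threshold) and fdr <= fdr_threshold, "down"
    for the mirror case, else "unchanged".
    """
    design = pd.Series(design)
    ctrl_cols = [s for s in counts.columns if design.get(s) == ctrl]
    treat_cols = [s for s in counts.columns if design.get(s) == treat]
    if len(ctrl_cols) < 2 or len(treat_cols) < 2:
        raise ValueError("need >= 2 samples per condition")
    libs = counts.sum(axis=0).astype(float)
    if (libs[ctrl_cols + treat_cols] == 0).any():
        raise ValueError("a sample has an all-zero library")
    norm = counts / libs * libs.mean()
    mc = norm[ctrl_cols].mean(axis=1)
    mt = norm[treat_cols].mean(axis=1)
    log2fc = np.log2(mt + 1) - np.log2(mc + 1)
    logn = np.log2(norm + 1)
    testfun = test or default_test
    p = np.asarray(testfun(logn[ctrl_cols].to_numpy(), logn[treat_cols].to_numpy()))
    fdr = bh_fdr(p)
    lfc_cut = np.log2(fc_threshold)
    status = np.where(
        (log2fc >= lfc_cut) & (fdr <= fdr_threshold),
        "up",
        np.where((log2fc <= -lfc_cut) & (fdr <= fdr_threshold), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "mean_ctrl": mc.to_numpy(),
            "mean_treat": mt.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "pvalue": p,
            "fdr": fdr,
            "status": status,
        }
    ).set_index("gene_id")


def ddct(
    records: Sequence[CtRecord], treat_group: str, ctrl_group: str
) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) per sample; ddCt is the difference of
    group mean dCts (treatment minus control); RQ = 2^-ddCt.  Swapping the
    groups maps RQ to 1/RQ.
    """
    d_treat = [r.ct_target - r.ct_ref for r in records if r.group == treat_group]
    d_ctrl = [r.ct_target - r.ct_ref for r in records if r.group == ctrl_group]
    if not d_treat or not d_ctrl:
        raise ValueError("both groups need >= 1 record")
    dd = float(np.mean(d_treat) - np.mean(d_ctrl))
    return {
        "dct_treat": float(np.mean(d_treat)),
        "dct_ctrl": float(np.mean(d_ctrl)),
        "ddct": dd,
        "rq": float(2.0 ** (-dd)),
    }


def sample_correlation(fpkm: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between samples on log2(FPKM + 1), plus the
    average-linkage dendrogram leaf order (distance 1 - r).

    Constant columns yield missing correlations and are placed last in the
    leaf order.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    log = np.log2(fpkm + 1)
    corr = log.corr(method="pearson")
    ok = [s for s in corr.columns if not corr[s].drop(s).isna().all()]
    bad = [s for s in corr.columns if s not in ok]
    if len(ok) >= 2:
        d = 1 - corr.loc[ok, ok].to_numpy()
        np.fill_diagonal(d, 0.0)
        order = leaves_list(linkage(squareform(d, checks=False), method="average"))
        leaf_order = [ok[i] for i in order] + bad
    else:
        leaf_order = list(corr.columns)
    return corr, leaf_order
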