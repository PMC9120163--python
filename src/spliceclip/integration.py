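"""Gene-set integration: Venn counts, the hypergeometric overlap test and
generic term enrichment with the count / factor / p-value threshold policy.

The overlap test is the upper-tail (accumulative) hypergeometric
probability of drawing at least k genes shared between a set of size K
and a set of size n from a universe of N genes, computed in log space via
the survival function.  Term enrichment applies the same test per term
against a user-supplied background, with BH q-values over all tested
terms; terms pass when p < p_threshold, count >= min_count and
enrichment factor > min_factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import pandas as pd
from scipy import stats

from .expression import bh_fdr


@dataclass(frozen=True)
class OverlapResult:
    """Upper-tail hypergeometric test of a two-set overlap."""

    set_a_size: int
    set_b_size: int
    overlap: int
    universe: int
    pvalue: float


def venn_counts(set_a: Set[str], set_b: Set[str]) -> tuple[int, int, int]:
    """(A only, overlap, B only) counts for a two-set Venn diagram."""
    inter = len(set_a & set_b)
    return len(set_a) - inter, inter, len(set_b) - inter


def hypergeometric_test(k: int, K: int, n: int, N: int) -> OverlapResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: observed overlap, K: size of set A, n: size of set B, N: universe.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent sizes k={k}, K={K}, n={n}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(K, n, k, N, min(p, 1.0))


def overlap_test(
    set_a: Set[str], set_b: Set[str], universe: Set[str]
) -> OverlapResult:
    """Hypergeometric overlap of two gene sets restricted to a universe."""
    a = set_a & universe
    b = set_b & universe
    return hypergeometric_test(len(a & b), len(a), len(b), len(universe))


def term_enrichment(
    gene_list: Set[str],
    term_map: Mapping[str, Set[str]],
    background: Set[str],
    p_threshold: float = 0.01,
    min_count: int = 3,
    min_factor: float = 1.5,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a gene list.

    expected = |gene_list| * |term ∩ background| / |background|;
    enrichment factor = observed count / expected.  q-values are BH over
    every tested term; the returned frame keeps only passing terms unless
    `return_all` is set (then a boolean `kept` column marks them).
    """
    if not background:
        raise ValueError("empty background")
    genes = set(gene_list) & background
    if set(gene_list) - background:
        raise ValueError("gene_list contains genes outside the background")
    N = len(background)
    rows = []
    for term_id in sorted(term_map):
        term_genes = set(term_map[term_id]) & background
        if not term_genes:
            continue
        count = len(genes & term_genes)
        expected = len(genes) * len(term_genes) / N
        res = hypergeometric_test(count, len(term_genes), len(genes), N)
        rows.append(
            {
                "term_id": term_id,
                "count": count,
                "term_size": len(term_genes),
                "expected": expected,
                "enrichment_factor": count / expected if expected > 0 else 0.0,
                "pvalue": res.pvalue,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "count", "term_size", "expected", "enrichment_factor", "pvalue", "qvalue", "kept"]
        )
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    df["kept"] = (
        (df["pvalue"] < p_threshold)
        & (df["count"] >= min_count)
        & (df["enrichment_factor"] > min_factor)
    )
    df = df.sort_values(["pvalue", "term_id"]).reset_index(drop=True)
    return df if return_all else df[df["kept"]].drop(columns="kept").reset_index(drop=True)
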