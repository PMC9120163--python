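"""Gene-set overlap and term enrichment.

The hypergeometric upper tail asks: drawing |B| genes from a universe of
N, how often would >= k land in a fixed set of size |A|?  Small p means
the two sets share more genes than chance allows.
"""

from spliceclip import hypergeometric_test, term_enrichment, venn_counts
from spliceclip.integration import overlap_test

# toy bound-gene and splicing-gene sets in a 1000-gene universe
universe = {f"g{i}" for i in range(1000)}
bound = {f"g{i}" for i in range(120)}            # 120 protein-bound genes
rasg = {f"g{i}" for i in range(80, 260)}          # 180 splicing-regulated genes
a_only, overlap, b_only = venn_counts(bound, rasg)
res = overlap_test(bound, rasg, universe)
print(f"Venn: {a_only} bound-only, {overlap} shared, {b_only} splicing-only")
print(f"hypergeometric P(X >= {overlap}) = {res.pvalue:.3e}")
# expected overlap by chance: 120*180/1000 = 21.6; observing 40 is a strong excess

# closed-form sanity point: drawing 5 of 10 with all 5 marked -> 1/C(10,5)
print("P(k=5 | K=5, n=5, N=10) =", hypergeometric_test(5, 5, 5, 10).pvalue)

# term enrichment with the count>=3 / factor>1.5 / p<0.01 policy
terms = {
    "immune_response": {f"g{i}" for i in range(90, 110)},
    "background_noise": {f"g{i}" for i in range(500, 700)},
}
enr = term_enrichment(bound, terms, universe)
print("\nenriched terms:")
print(enr.to_string(index=False))
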