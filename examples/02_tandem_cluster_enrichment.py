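"""Test enrichment of tandem receptor-gene clusters in dense LINE arrays.

Simulates gene annotations twice - once with clusters placed uniformly
(the null) and once seeded into arrays at ten-fold weight - and runs the
randomization binomial test against 500 random length-matched regions.
"""

import l1array as la
from l1array.scan import ArrayRegion

genome = {f"chr{i}": 10_000_000 for i in range(1, 9)}

for label, factor in (("null (uniform clusters)", 1.0), ("10x enrichment", 10.0)):
    config = la.SimConfig(
        genome=genome, n_arrays=66, array_length=150_000,
        n_background_genes=260, n_clusters=120, enrichment_factor=factor,
    )
    bundle = la.simulate_annotation(config, seed=11, parts=("genes",))
    regions = [ArrayRegion(a.chrom, a.start, a.end) for a in bundle.truth.arrays]
    res = la.cluster_enrichment(
        regions, bundle.genes, "^Olfr", bundle.genome, n_random=500, seed=11
    )
    print(f"{label}:")
    print(
        f"  {res.k_observed}/{res.n_regions} arrays contain an Olfr-cluster gene; "
        f"background {res.k_background}/{res.n_random} random regions "
        f"(p_hat={res.p_hat:.3f})"
    )
    print(f"  exact binomial upper tail: p = {res.p_value:.3g}\n")

print(
    "Under the null the observed containment rate matches the random-region"
    "\nbackground (p is large); with clusters seeded into arrays the excess is"
    "\nhighly significant."
)
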