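"""Classify arrays by lamina association and stratify L1s by lineage.

LAD tracks for four cell types each cover a random half of the planted
arrays; overlap of at least 10 kb with a cell type's (unioned) LADs counts.
Lineage labels come from subfamily-name prefix rules; elements are
assigned to arrays by their midpoints.
"""

import l1array as la
from l1array.scan import ArrayRegion

config = la.SimConfig(
    genome={"chr1": 5_000_000, "chr2": 5_000_000},
    n_arrays=12,
    array_lineage_mix={"Eutherian": 0.06, "Rodent": 0.13,
                       "Muridae": 0.34, "Mus": 0.47},
)
bundle = la.simulate_annotation(config, seed=5)
regions = [ArrayRegion(a.chrom, a.start, a.end) for a in bundle.truth.arrays]

records, summary = la.lad_overlap(regions, bundle.lads, min_overlap=10_000)
print(
    f"LADs across {len(bundle.lads.cell_types)} cell types: "
    f"{summary.n_any}/{summary.n_regions} arrays lamina-associated "
    f"({summary.n_constitutive} constitutive, {summary.n_facultative} "
    f"facultative, {summary.n_none} none)\n"
)

table = la.lineage_stratify(bundle.repeats, regions, la.LineageMap.default_mouse())
print(f"{'lineage':>10} {'genome-wide':>12} {'in arrays':>10} {'outside':>8}")
for lin in table.lineages:
    print(
        f"{lin:>10} {table.genomewide[lin]:>12} "
        f"{table.within_arrays[lin]:>10} {table.outside_arrays[lin]:>8}"
    )
ratios = table.ratios_within()
print(
    "\nin-array ratios vs Eutherian: "
    + " : ".join(f"{ratios[lin]:.1f}" for lin in table.lineages)
)
print(
    "The young (Mus, Muridae) subfamilies dominate inside arrays while the\n"
    "genome-wide pool is near-uniform - the planted mixture is recovered."
)
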