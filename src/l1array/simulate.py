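"""Seeded generators for annotation bundles and L1 sequences with known truth.

The annotation generator emulates the statistical structure the scanning
and enrichment stages assume: a genome with diffuse background LINE
coverage at fraction ``p0``, non-overlapping planted arrays of controlled
length with coverage ``p1``, tandem gene clusters placed into arrays at a
configurable enrichment factor, per-cell-type LAD tracks covering a random
subset of arrays, and lineage labels drawn per element from
stratum-specific mixtures.  Every quantity needed by downstream truth
comparisons is recorded in a :class:`TruthSet`; emitted files are exactly
the formats the IO module reads and are byte-identical per (config, seed).

Repeat placement is a marked point process: elements (geometric lengths,
uniform starts, overlaps allowed - as in real RepeatMasker tracks) are
added to each genomic segment until its union coverage reaches the target
fraction, so realized coverage matches the target to within one element
length.  Tandem clusters are placed by rejection weighting: a uniform
proposal is accepted with weight ``enrichment_factor`` when the cluster
falls entirely inside an array and weight 1 otherwise, so factor 1 is
EXACTLY uniform placement (the null configuration for type-I calibration).

The sequence generator builds a designed L1 consensus (stop-free random
codons in ORF1/ORF2, AATAAA near the 3' end) and injects controlled
defects - premature stops, a frameshift, 5' truncation, poly(A) mutation,
background substitutions - each verified to produce its intended lesion.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .intervals import Interval, IntervalSet
from .io import (
    GenomeMap,
    GeneFeature,
    LADCollection,
    RepeatFeature,
    write_bed_track,
    write_chrom_sizes,
    write_repeats_ucsc,
    BedRecord,
)
from .intactness import ElementSpec, find_orfs

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimBundle",
    "simulate_annotation",
    "simulate_l1_fasta",
    "DEFECT_TYPES",
]

# subfamily name pools per lineage; names chosen so the default LineageMap
# prefix rules recover the intended label
_L1_NAME_POOLS: dict[str, tuple[str, ...]] = {
    "Mus": ("L1Md_Tf", "L1Md_A", "L1Md_Gf", "L1Md_F2"),
    "Muridae": ("Lx2", "Lx3", "Lx4", "Lx5"),
    "Rodent": ("L1_Mur1", "L1_Mur2", "L1_Mur3"),
    "Eutherian": ("L1ME1", "L1MB5", "L1MA6", "L1MC3"),
}
_DIV_BY_LINEAGE = {"Mus": 80, "Muridae": 150, "Rodent": 200, "Eutherian": 250}
_OTHER_NAME_POOLS: dict[str, tuple[tuple[str, str], ...]] = {
    "SINE": (("B1_Mus1", "Alu"), ("B2_Mm1a", "B2")),
    "LTR": (("RLTR10", "ERVK"), ("MTA_Mm", "ERVL-MaLR")),
    "DNA": (("Tigger1", "TcMar-Tigger"),),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic annotation bundle.

    Densities are union-coverage fractions; ``array_lineage_mix`` and
    ``background_lineage_mix`` are proportions over lineage labels and must
    each sum to 1.  ``enrichment_factor`` weights tandem-cluster placement
    into arrays (1 = uniform/null).  ``lad_cover_prob`` is the per-cell-type
    probability that a planted array is covered by a LAD.
    """

    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000}
    )
    background_density: float = 0.20
    repeat_mean_length: int = 600
    n_arrays: int = 10
    array_length: int = 150_000
    array_density: float = 0.85
    array_min_gap: int = 100_000
    array_lineage_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Eutherian": 0.06, "Rodent": 0.13, "Muridae": 0.34, "Mus": 0.47,
        }
    )
    background_lineage_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Eutherian": 0.25, "Rodent": 0.25, "Muridae": 0.25, "Mus": 0.25,
        }
    )
    other_class_density: dict[str, float] = field(
        default_factory=lambda: {"SINE": 0.08, "LTR": 0.04}
    )
    n_background_genes: int = 40
    gene_mean_length: int = 15_000
    n_clusters: int = 6
    cluster_size: int = 6
    cluster_gene_length: int = 1_500
    cluster_gene_gap: int = 500
    cluster_family: str = "Olfr"
    enrichment_factor: float = 1.0
    cell_types: tuple[str, ...] = ("ESC", "NPC", "AST", "MEF")
    lad_cover_prob: float = 0.5
    lad_flank: int = 20_000
    n_decoy_lads: int = 10
    decoy_lad_length: int = 150_000
    decoy_lad_margin: int = 50_000

    def __post_init__(self) -> None:
        for name, val in (
            ("background_density", self.background_density),
            ("array_density", self.array_density),
            ("lad_cover_prob", self.lad_cover_prob),
        ):
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")
        for mix_name, mix in (
            ("array_lineage_mix", self.array_lineage_mix),
            ("background_lineage_mix", self.background_lineage_mix),
        ):
            if mix and abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{mix_name} proportions must sum to 1")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1 (1 = null/uniform)")
        if not self.genome:
            raise ValueError("empty genome")

    @property
    def cluster_span(self) -> int:
        return (
            self.cluster_size * self.cluster_gene_length
            + (self.cluster_size - 1) * self.cluster_gene_gap
        )


@dataclass
class GeneTruth:
    name: str
    chrom: str
    start: int
    end: int
    family: str | None
    in_array: bool
    array_id: int | None


@dataclass
class TruthSet:
    """Ground truth of one simulated bundle (sufficient for every
    downstream truth comparison; nothing need be re-derived from files)."""

    arrays: list[Interval]
    realized_array_density: list[float]
    realized_background_density: dict[str, float]
    genes: list[GeneTruth]
    lad_covered: dict[str, list[int]]          # cell type -> planted array ids
    element_lineages: list[str | None]         # parallel to SimBundle.repeats

    def to_json(self, path: str | Path) -> None:
        import math

        payload = {
            "arrays": [[iv.chrom, iv.start, iv.end] for iv in self.arrays],
            "realized_array_density": [
                None if math.isnan(d) else d for d in self.realized_array_density
            ],
            "realized_background_density": self.realized_background_density,
            "genes": [asdict(g) for g in self.genes],
            "lad_covered": self.lad_covered,
            "element_lineages": self.element_lineages,
        }
        with open(path, "wt", encoding="ascii") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path, "rt", encoding="ascii") as fh:
            payload = json.load(fh)
        return cls(
            arrays=[Interval(c, s, e) for c, s, e in payload["arrays"]],
            realized_array_density=[
                float("nan") if d is None else d
                for d in payload["realized_array_density"]
            ],
            realized_background_density=payload["realized_background_density"],
            genes=[GeneTruth(**g) for g in payload["genes"]],
            lad_covered={k: list(v) for k, v in payload["lad_covered"].items()},
            element_lineages=payload["element_lineages"],
        )


@dataclass
class SimBundle:
    config: SimConfig
    seed: int
    genome: GenomeMap
    repeats: list[RepeatFeature]
    genes: list[GeneFeature]
    lads: LADCollection | None
    truth: TruthSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": outdir / "genome.chrom.sizes",
            "repeats": outdir / "repeats.rmsk.tsv",
            "genes": outdir / "genes.bed",
            "truth": outdir / "truth.json",
        }
        write_chrom_sizes(self.genome, paths["chrom_sizes"])
        write_repeats_ucsc(self.repeats, paths["repeats"], self.genome)
        write_bed_track(
            [
                BedRecord(g.chrom, g.start, g.end, g.name, 0, g.strand)
                for g in self.genes
            ],
            paths["genes"],
        )
        if self.lads is not None:
            for ct, track in self.lads.tracks.items():
                p = outdir / f"lads_{ct}.bed"
                write_bed_track(list(track), p)
                paths[f"lads_{ct}"] = p
        self.truth.to_json(paths["truth"])
        return paths


def _place_arrays(config: SimConfig, rng: np.random.Generator) -> list[Interval]:
    entries = list(config.genome.items())
    names = [c for c, _ in entries]
    sizes = np.asarray([l for _, l in entries], dtype=np.float64)
    L, gap = config.array_length, config.array_min_gap
    w = np.maximum(0.0, sizes - L + 1)
    if w.sum() == 0:
        raise ValueError("planted arrays do not fit: every chromosome shorter than array")
    cum = np.cumsum(w / w.sum())
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    out: list[Interval] = []
    for _ in range(config.n_arrays):
        for _ in range(2000):
            ci = min(int(np.searchsorted(cum, rng.random(), side="right")), len(names) - 1)
            clen = int(sizes[ci])
            if clen < L:
                continue
            start = int(rng.integers(0, clen - L + 1))
            ok = all(
                start - gap >= e or start + L + gap <= s
                for s, e in placed[names[ci]]
            )
            if ok:
                placed[names[ci]].append((start, start + L))
                out.append(Interval(names[ci], start, start + L))
                break
        else:
            raise ValueError(
                "planted arrays do not fit inside the genome at the requested "
                "count, length and minimum gap"
            )
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def _fill_segment(
    rng: np.random.Generator,
    seg_start: int,
    seg_len: int,
    density: float,
    mean_len: int,
) -> tuple[list[tuple[int, int]], float]:
    """Add elements until union coverage of the segment reaches the target.

    Returns (element intervals, realized coverage fraction).
    """
    if seg_len <= 0 or density <= 0.0:
        return [], 0.0
    if density >= 1.0:
        return [(seg_start, seg_start + seg_len)], 1.0
    target = density * seg_len
    mask = np.zeros(seg_len, dtype=bool)
    covered = 0
    out: list[tuple[int, int]] = []
    while covered < target:
        s = int(rng.integers(0, seg_len))
        l = int(rng.geometric(1.0 / mean_len))
        e = min(seg_len, s + l)
        view = mask[s:e]
        new = (e - s) - int(view.sum())
        view[:] = True
        covered += new
        out.append((seg_start + s, seg_start + e))
    return out, covered / seg_len


def _draw_lineage(rng: np.random.Generator, mix: dict[str, float]) -> str:
    labels = list(mix)
    probs = np.asarray([mix[l] for l in labels])
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def _simulate_repeats(
    config: SimConfig,
    arrays: list[Interval],
    rng: np.random.Generator,
) -> tuple[list[RepeatFeature], list[str | None], list[float], dict[str, float]]:
    feats: list[tuple[RepeatFeature, str | None]] = []
    realized_by_array: dict[tuple[str, int], float] = {}
    realized_bg: dict[str, float] = {}
    arrays_by_chrom: dict[str, list[Interval]] = {}
    for iv in arrays:
        arrays_by_chrom.setdefault(iv.chrom, []).append(iv)

    def add_l1(intervals: list[tuple[int, int]], chrom: str, mix: dict[str, float]):
        for s, e in intervals:
            lin = _draw_lineage(rng, mix)
            name = _L1_NAME_POOLS[lin][int(rng.integers(0, len(_L1_NAME_POOLS[lin])))]
            div = int(np.clip(rng.normal(_DIV_BY_LINEAGE[lin], 30), 0, 400))
            feats.append(
                (
                    RepeatFeature(
                        chrom=chrom, start=s, end=e,
                        strand="+" if rng.random() < 0.5 else "-",
                        rep_name=name, rep_class="LINE", rep_family="L1",
                        divergence=div,
                    ),
                    lin,
                )
            )

    for chrom, clen in config.genome.items():
        chrom_arrays = arrays_by_chrom.get(chrom, [])
        # background segments = gaps between arrays
        edges = [0]
        for iv in chrom_arrays:
            edges += [iv.start, iv.end]
        edges.append(clen)
        bg_covered = bg_len = 0
        for i in range(0, len(edges), 2):
            seg_start, seg_end = edges[i], edges[i + 1]
            seg_len = seg_end - seg_start
            ivs, frac = _fill_segment(
                rng, seg_start, seg_len, config.background_density,
                config.repeat_mean_length,
            )
            add_l1(ivs, chrom, config.background_lineage_mix)
            bg_covered += frac * seg_len
            bg_len += seg_len
        realized_bg[chrom] = (bg_covered / bg_len) if bg_len else 0.0
        for iv in chrom_arrays:
            ivs, frac = _fill_segment(
                rng, iv.start, iv.length, config.array_density,
                config.repeat_mean_length,
            )
            add_l1(ivs, chrom, config.array_lineage_mix)
            realized_by_array[(iv.chrom, iv.start)] = frac
        # other repeat classes: uniform across the whole chromosome
        for cls, dens in config.other_class_density.items():
            ivs, _ = _fill_segment(rng, 0, clen, dens, config.repeat_mean_length)
            pool = _OTHER_NAME_POOLS.get(cls, ((f"{cls}_sim", cls),))
            for s, e in ivs:
                name, fam = pool[int(rng.integers(0, len(pool)))]
                feats.append(
                    (
                        RepeatFeature(
                            chrom=chrom, start=s, end=e,
                            strand="+" if rng.random() < 0.5 else "-",
                            rep_name=name, rep_class=cls, rep_family=fam,
                            divergence=int(rng.integers(100, 300)),
                        ),
                        None,
                    )
                )

    realized_array = [realized_by_array[(iv.chrom, iv.start)] for iv in arrays]
    feats.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    features = [f for f, _ in feats]
    lineages = [lin for _, lin in feats]
    return features, lineages, realized_array, realized_bg


def _simulate_genes(
    config: SimConfig,
    arrays: list[Interval],
    rng: np.random.Generator,
) -> tuple[list[GeneFeature], list[GeneTruth]]:
    entries = list(config.genome.items())
    names = [c for c, _ in entries]
    sizes = np.asarray([l for _, l in entries], dtype=np.float64)
    cum = np.cumsum(sizes / sizes.sum())
    arrays_by_chrom: dict[str, list[Interval]] = {}
    for i, iv in enumerate(arrays):
        arrays_by_chrom.setdefault(iv.chrom, []).append(iv)
    array_index = {(iv.chrom, iv.start): i for i, iv in enumerate(arrays)}

    genes: list[GeneFeature] = []
    truth: list[GeneTruth] = []

    for i in range(config.n_background_genes):
        glen = max(200, int(rng.geometric(1.0 / config.gene_mean_length)))
        ci = min(int(np.searchsorted(cum, rng.random(), side="right")), len(names) - 1)
        clen = int(sizes[ci])
        glen = min(glen, clen // 2)  # a gene cannot outgrow its chromosome
        start = int(rng.integers(0, clen - glen + 1))
        g = GeneFeature(
            chrom=names[ci], start=start, end=start + glen,
            strand="+" if rng.random() < 0.5 else "-",
            name=f"Gm{i + 1:04d}",
        )
        genes.append(g)
        truth.append(GeneTruth(g.name, g.chrom, g.start, g.end, None, False, None))

    span = config.cluster_span
    ef = config.enrichment_factor
    gene_counter = 0
    for _ in range(config.n_clusters):
        for _ in range(100_000):
            ci = min(int(np.searchsorted(cum, rng.random(), side="right")), len(names) - 1)
            clen = int(sizes[ci])
            if span >= clen:
                continue
            start = int(rng.integers(0, clen - span + 1))
            chrom = names[ci]
            inside = None
            for iv in arrays_by_chrom.get(chrom, ()):
                if iv.start <= start and start + span <= iv.end:
                    inside = iv
                    break
            weight = ef if inside is not None else 1.0
            if rng.random() < weight / ef:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place tandem cluster")
        aid = array_index[(inside.chrom, inside.start)] if inside is not None else None
        strand = "+" if rng.random() < 0.5 else "-"
        for j in range(config.cluster_size):
            gs = start + j * (config.cluster_gene_length + config.cluster_gene_gap)
            ge = gs + config.cluster_gene_length
            gene_counter += 1
            g = GeneFeature(
                chrom=chrom, start=gs, end=ge, strand=strand,
                name=f"{config.cluster_family}{gene_counter:04d}",
                family=config.cluster_family,
            )
            genes.append(g)
            truth.append(
                GeneTruth(
                    g.name, g.chrom, g.start, g.end, config.cluster_family,
                    inside is not None, aid,
                )
            )
    order = sorted(range(len(genes)), key=lambda i: (genes[i].chrom, genes[i].start, genes[i].name))
    return [genes[i] for i in order], [truth[i] for i in order]


def _simulate_lads(
    config: SimConfig,
    arrays: list[Interval],
    rng: np.random.Generator,
) -> tuple[LADCollection, dict[str, list[int]]]:
    entries = list(config.genome.items())
    names = [c for c, _ in entries]
    sizes = np.asarray([l for _, l in entries], dtype=np.float64)
    cum = np.cumsum(sizes / sizes.sum())
    margin = config.decoy_lad_margin
    expanded = IntervalSet.from_tuples(
        (iv.chrom, max(0, iv.start - margin), iv.end + margin) for iv in arrays
    )
    tracks: dict[str, IntervalSet] = {}
    covered: dict[str, list[int]] = {}
    for ct in config.cell_types:
        intervals: list[tuple[str, int, int]] = []
        ids: list[int] = []
        for i, iv in enumerate(arrays):
            if rng.random() < config.lad_cover_prob:
                ids.append(i)
                clen = config.genome[iv.chrom]
                intervals.append(
                    (iv.chrom, max(0, iv.start - config.lad_flank),
                     min(clen, iv.end + config.lad_flank))
                )
        n_placed = 0
        tries = 0
        while n_placed < config.n_decoy_lads and tries < 100_000:
            tries += 1
            ci = min(int(np.searchsorted(cum, rng.random(), side="right")), len(names) - 1)
            clen = int(sizes[ci])
            llen = min(config.decoy_lad_length, clen)
            start = int(rng.integers(0, clen - llen + 1))
            if bool(expanded.overlaps(names[ci], start, start + llen)[0]):
                continue
            intervals.append((names[ci], start, start + llen))
            n_placed += 1
        covered[ct] = ids
        tracks[ct] = IntervalSet.from_tuples(intervals) if intervals else IntervalSet()
    return LADCollection(tracks), covered


def simulate_annotation(
    config: SimConfig,
    seed: int,
    outdir: str | Path | None = None,
    parts: Sequence[str] = ("repeats", "genes", "lads"),
) -> SimBundle:
    """Generate one annotation bundle with known truth.

    ``parts`` restricts which annotation layers are generated (planted
    arrays are always placed); generating fewer layers is cheaper and keeps
    the random stream of each layer independent of the others, because each
    layer draws from its own child generator.
    """
    unknown = set(parts) - {"repeats", "genes", "lads"}
    if unknown:
        raise ValueError(f"unknown annotation parts: {sorted(unknown)}")
    genome = GenomeMap(config.genome)
    root = np.random.SeedSequence(seed)
    rng_arrays, rng_repeats, rng_genes, rng_lads = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    arrays = _place_arrays(config, rng_arrays)

    repeats: list[RepeatFeature] = []
    lineages: list[str | None] = []
    realized_array: list[float] = [float("nan")] * len(arrays)
    realized_bg: dict[str, float] = {}
    if "repeats" in parts:
        repeats, lineages, realized_array, realized_bg = _simulate_repeats(
            config, arrays, rng_repeats
        )
    genes: list[GeneFeature] = []
    gene_truth: list[GeneTruth] = []
    if "genes" in parts:
        genes, gene_truth = _simulate_genes(config, arrays, rng_genes)
    lads = None
    lad_covered: dict[str, list[int]] = {}
    if "lads" in parts:
        lads, lad_covered = _simulate_lads(config, arrays, rng_lads)

    truth = TruthSet(
        arrays=arrays,
        realized_array_density=realized_array,
        realized_background_density=realized_bg,
        genes=gene_truth,
        lad_covered=lad_covered,
        element_lineages=lineages,
    )
    bundle = SimBundle(
        config=config, seed=seed, genome=genome, repeats=repeats,
        genes=genes, lads=lads, truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


# ---------------------------------------------------------------------------
# L1 sequence simulation
# ---------------------------------------------------------------------------

DEFECT_TYPES = (
    "inject_stop_orf1",
    "inject_stop_orf2",
    "frameshift",
    "truncate",
    "mutate_polya",
)

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


@dataclass(frozen=True)
class _Layout:
    utr5: int
    orf1_start: int
    orf1_aa: int          # aa codons including the initial Met
    orf2_start: int
    orf2_aa: int
    polya_pos: int        # offset of the designed AATAAA
    total: int


def _design_layout(spec: ElementSpec) -> _Layout:
    utr5 = max(200, int(0.15 * spec.expected_length))
    orf1_aa = max(350, spec.orf1_min_aa + 50)
    orf2_aa = max(1280, spec.orf2_min_aa + 80)
    spacer = 60
    orf1_len = 3 * (orf1_aa + 1)
    orf2_start = utr5 + orf1_len + spacer
    orf2_len = 3 * (orf2_aa + 1)
    total = spec.expected_length
    utr3 = total - orf2_start - orf2_len
    if utr3 < spec.polya_window:
        raise ValueError(
            "expected_length too small for the designed ORF1/ORF2 architecture"
        )
    if utr5 > spec.orf1_search_window * total:
        raise ValueError("designed ORF1 would start outside the search window")
    return _Layout(
        utr5=utr5,
        orf1_start=utr5,
        orf1_aa=orf1_aa,
        orf2_start=orf2_start,
        orf2_aa=orf2_aa,
        polya_pos=total - spec.polya_window // 2,
        total=total,
    )


def _random_orf(rng: np.random.Generator, n_aa: int) -> str:
    codons = ["ATG"]
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_aa - 1)
    codons += [_SENSE_CODONS[int(i)] for i in idx]
    codons.append(_STOPS[int(rng.integers(0, 3))])
    return "".join(codons)


def _scrub_polya(seq: list[str], spec: ElementSpec, keep: int, rng) -> None:
    """Remove spurious poly(A) signals from the 3' window, keeping the
    designed occurrence at offset ``keep``."""
    motif = spec.polya_signal
    n = len(seq)
    lo = n - spec.polya_window
    changed = True
    while changed:
        changed = False
        tail = "".join(seq[lo:])
        pos = tail.find(motif)
        while pos != -1:
            abs_pos = lo + pos
            if abs_pos != keep:
                off = int(rng.integers(0, len(motif)))
                cur = seq[abs_pos + off]
                seq[abs_pos + off] = _BASES[(_BASES.index(cur) + 1) % 4]
                changed = True
                break
            pos = tail.find(motif, pos + 1)


def _spurious_orfs(seq: str, spec: ElementSpec, lay: _Layout) -> bool:
    """True if the sequence carries any long stop-terminated ORF other than
    the two designed ones (random UTRs can create them with tiny but
    nonzero probability)."""
    for o in find_orfs(seq, min_aa=spec.orf1_min_aa):
        if not o.stop_codon:
            continue
        designed = o.start in (lay.orf1_start, lay.orf2_start)
        if not designed:
            return True
        if o.start == lay.orf1_start and o.length_aa != lay.orf1_aa:
            return True
        if o.start == lay.orf2_start and o.length_aa != lay.orf2_aa:
            return True
    return False


def _build_consensus(spec: ElementSpec, rng: np.random.Generator) -> tuple[str, _Layout]:
    lay = _design_layout(spec)
    for _ in range(100):
        seq = [_BASES[int(i)] for i in rng.integers(0, 4, size=lay.total)]
        orf1 = _random_orf(rng, lay.orf1_aa)
        seq[lay.orf1_start : lay.orf1_start + len(orf1)] = list(orf1)
        orf2 = _random_orf(rng, lay.orf2_aa)
        seq[lay.orf2_start : lay.orf2_start + len(orf2)] = list(orf2)
        seq[lay.polya_pos : lay.polya_pos + len(spec.polya_signal)] = list(
            spec.polya_signal
        )
        _scrub_polya(seq, spec, lay.polya_pos, rng)
        if not _spurious_orfs("".join(seq), spec, lay):
            return "".join(seq), lay
    raise RuntimeError("could not build a consensus free of spurious long ORFs")


def _has_long_orf(seq: str, min_aa: int, lo: int = 0, hi: int | None = None) -> bool:
    return any(
        o.stop_codon
        and o.length_aa >= min_aa
        and o.start >= lo
        and (hi is None or o.start < hi)
        for o in find_orfs(seq, min_aa=min_aa)
    )


def _inject_stop(
    seq: list[str], lay: _Layout, spec: ElementSpec, which: str, rng
) -> list[str]:
    if which == "orf1":
        start_nt, n_aa, min_keep = lay.orf1_start, lay.orf1_aa, spec.orf1_min_aa
    else:
        start_nt, n_aa, min_keep = lay.orf2_start, lay.orf2_aa, spec.orf2_min_aa
    # prefix (j aa) and any restart ORF (<= n_aa-1-j aa) must both fall
    # below the threshold, which pins j into [n_aa - min_keep, min_keep - 1]
    lo, hi = n_aa - min_keep, min_keep - 1
    for _ in range(50):
        j = int(rng.integers(lo, hi + 1))
        pos = start_nt + 3 * j
        trial = list(seq)
        trial[pos : pos + 3] = list(_STOPS[int(rng.integers(0, 3))])
        joined = "".join(trial)
        if which == "orf1":
            broken = not _has_long_orf(
                joined, spec.orf1_min_aa, hi=lay.orf2_start
            )
        else:
            broken = not _has_long_orf(joined, spec.orf2_min_aa)
        if broken:
            return trial
    raise RuntimeError(f"stop injection failed to destroy {which}")


def _apply_frameshift(
    seq: list[str], lay: _Layout, spec: ElementSpec, rng
) -> list[str]:
    # single-base deletion early enough in ORF2 that neither the shifted
    # read-through nor any downstream restart reaches orf2_min_aa; verified
    # and redrawn if a long ORF survives by chance
    for _ in range(50):
        j = int(rng.integers(lay.orf2_aa - spec.orf2_min_aa, spec.orf2_min_aa - 60))
        pos = lay.orf2_start + 3 * j + int(rng.integers(0, 3))
        trial = seq[:pos] + seq[pos + 1 :]
        if not _has_long_orf("".join(trial), spec.orf2_min_aa):
            return trial
    raise RuntimeError("frameshift injection failed to destroy ORF2")


def _mutate_polya(seq: list[str], lay: _Layout, spec: ElementSpec, rng) -> None:
    for _ in range(50):
        off = int(rng.integers(0, len(spec.polya_signal)))
        pos = lay.polya_pos + off
        cur = seq[pos]
        choices = [b for b in _BASES if b != cur]
        seq[pos] = choices[int(rng.integers(0, 3))]
        tail = "".join(seq[len(seq) - spec.polya_window :])
        if spec.polya_signal not in tail:
            return
    raise RuntimeError("poly(A) mutation failed to remove the signal")


@dataclass(frozen=True)
class ElementTruth:
    element_id: str
    defects: tuple[str, ...]
    length: int


def simulate_l1_fasta(
    n: int,
    spec: ElementSpec = ElementSpec(),
    defect_plan: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
    mu: float = 0.0,
    truncate_fraction: float = 0.5,
    fasta_path: str | Path | None = None,
) -> tuple[list[SeqRecord], list[ElementTruth]]:
    """Generate ``n`` L1 sequences from a designed consensus with controlled
    defects.

    ``defect_plan[i]`` lists the defects of element ``i`` (names from
    :data:`DEFECT_TYPES`); ``None`` means all elements are defect-free.
    ``mu`` adds background substitutions at the given per-base rate before
    any targeted defect.  Deterministic per (inputs, seed).
    """
    if defect_plan is not None and len(defect_plan) != n:
        raise ValueError("defect_plan must have one entry per element")
    if defect_plan is not None:
        for i, defects in enumerate(defect_plan):
            bad = set(defects) - set(DEFECT_TYPES)
            if bad:
                raise ValueError(
                    f"element {i}: unknown defect(s) {sorted(bad)}; "
                    f"known: {DEFECT_TYPES}"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    consensus, lay = _build_consensus(spec, rng)

    records: list[SeqRecord] = []
    truths: list[ElementTruth] = []
    for i in range(n):
        defects = tuple(defect_plan[i]) if defect_plan is not None else ()
        seq = list(consensus)
        if mu > 0:
            hits = np.flatnonzero(rng.random(len(seq)) < mu)
            for pos in hits:
                cur = seq[pos]
                choices = [b for b in _BASES if b != cur]
                seq[int(pos)] = choices[int(rng.integers(0, 3))]
        if "inject_stop_orf1" in defects:
            seq = _inject_stop(seq, lay, spec, "orf1", rng)
        if "inject_stop_orf2" in defects:
            seq = _inject_stop(seq, lay, spec, "orf2", rng)
        if "frameshift" in defects:
            seq = _apply_frameshift(seq, lay, spec, rng)
        if "mutate_polya" in defects:
            _mutate_polya(seq, lay, spec, rng)
        if "truncate" in defects:
            keep = int(len(seq) * truncate_fraction)
            seq = seq[len(seq) - keep :]  # 5' truncation, the common L1 lesion
        element_id = f"L1sim_{i + 1:04d}"
        records.append(
            SeqRecord(Seq("".join(seq)), id=element_id, description="")
        )
        truths.append(ElementTruth(element_id, defects, len(seq)))
    if fasta_path is not None:
        SeqIO.write(records, str(fasta_path), "fasta")
    return records, truths
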