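"""Readers and writers for the annotation formats the pipeline touches.

Everything is normalized on read to one internal convention: 0-based,
half-open coordinates, features sorted by ``(chrom, start)``.  RepeatMasker
``.out`` files use 1-based inclusive query coordinates and are converted
with ``start = begin - 1``; UCSC ``rmsk`` tables and BED are already
half-open.  Features on chromosomes absent from the genome map, or with
coordinates outside it, are rejected with an error rather than silently
dropped or clipped.

Supported formats
-----------------
* ``chrom.sizes``: two whitespace-separated columns, order preserved.
* RepeatMasker ``.out``: 15+ whitespace columns after the standard three
  header lines; ``C`` strand is read as ``-``; trailing ``*`` (element
  overlapped by a better match) is kept.
* UCSC ``rmsk`` TSV: tab-separated, 16 columns or 17 with a leading ``bin``
  column; ``#``-prefixed header lines are skipped.
* BED3/BED6 tracks (genes, LADs, regions); for repeats in BED, the name
  column carries ``rep_name|rep_class|rep_family``.

Plain gzip input (``.gz``) is transparent for all readers.
"""

from __future__ import annotations

import gzip
import io as _io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .intervals import Interval, IntervalSet

__all__ = [
    "GenomeMap",
    "RepeatFeature",
    "GeneFeature",
    "BedRecord",
    "LADCollection",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_repeats",
    "write_repeats_ucsc",
    "read_bed_track",
    "write_bed_track",
    "read_genes",
    "write_region_report",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


class GenomeMap:
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, entries: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._entries: dict[str, int] = {}
        for name, length in items:
            if name in self._entries:
                raise ValueError(f"duplicate chromosome {name!r}")
            length = int(length)
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._entries[name] = length
        if not self._entries:
            raise ValueError("no chromosomes")

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> int:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeMap) and list(self.items()) == list(other.items())

    def items(self):
        return self._entries.items()

    def total_size(self) -> int:
        return sum(self._entries.values())

    def __repr__(self) -> str:
        return f"GenomeMap({len(self)} chromosomes, {self.total_size():,} bp)"


def read_chrom_sizes(path: str | Path) -> GenomeMap:
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            name, raw = fields[0], fields[1]
            try:
                length = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {raw!r}"
                ) from None
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            entries.append((name, length))
    if not entries:
        raise ValueError(f"{path}: no chromosomes")
    return GenomeMap(entries)


def write_chrom_sizes(genome: GenomeMap, path: str | Path) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True, slots=True)
class RepeatFeature:
    """One annotated repeat element (RepeatMasker three-level taxonomy)."""

    chrom: str
    start: int
    end: int
    strand: str = "?"
    rep_name: str = ""
    rep_class: str = ""
    rep_family: str = ""
    lineage: str | None = None
    divergence: int | None = None  # milliDiv, 0-1000

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid repeat coordinates {self.chrom}:{self.start}-{self.end}"
            )
        if not self.rep_class:
            raise ValueError(f"repeat at {self.chrom}:{self.start} has empty rep_class")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class GeneFeature:
    chrom: str
    start: int
    end: int
    strand: str = "?"
    name: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid gene coordinates {self.chrom}:{self.start}-{self.end}"
            )
        if not self.name:
            raise ValueError(f"gene at {self.chrom}:{self.start} has empty name")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass(frozen=True, slots=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None


def _validate_against_genome(features, genome: GenomeMap | None, what: str) -> None:
    if genome is None:
        return
    missing = sorted({f.chrom for f in features if f.chrom not in genome})
    if missing:
        raise ValueError(
            f"{what} on chromosomes absent from the genome map: {', '.join(missing)}"
        )
    for f in features:
        if f.end > genome[f.chrom]:
            raise ValueError(
                f"{what} {f.chrom}:{f.start}-{f.end} extends beyond chromosome "
                f"length {genome[f.chrom]}"
            )


def _parse_rmsk_out_line(fields: list[str], lineno: int, path) -> RepeatFeature:
    # standard columns: sw_score perc_div perc_del perc_ins query q_begin q_end
    # q_left strand rep_name rep_class/family r_begin r_end r_left id [*]
    chrom = fields[4]
    begin, end = int(fields[5]), int(fields[6])
    start = begin - 1  # 1-based inclusive -> 0-based half-open
    if end <= start:
        raise ValueError(f"{path}:{lineno}: end {end} <= start after conversion")
    strand = "-" if fields[8] == "C" else fields[8]
    cls_fam = fields[10].split("/", 1)
    divergence = int(round(float(fields[1]) * 10))  # percent -> milliDiv
    return RepeatFeature(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        rep_name=fields[9],
        rep_class=cls_fam[0],
        rep_family=cls_fam[1] if len(cls_fam) > 1 else "",
        divergence=divergence,
    )


def _parse_ucsc_rmsk_line(fields: list[str], lineno: int, path) -> RepeatFeature:
    if len(fields) >= 17:
        fields = fields[1:]  # drop leading bin column
    if len(fields) < 13:
        raise ValueError(f"{path}:{lineno}: expected >=16 tab-separated columns")
    start, end = int(fields[5]), int(fields[6])
    if end <= start:
        raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
    return RepeatFeature(
        chrom=fields[4],
        start=start,
        end=end,
        strand=fields[8],
        rep_name=fields[9],
        rep_class=fields[10],
        rep_family=fields[11],
        divergence=int(fields[1]),
    )


def _parse_bed_repeat_line(fields: list[str], lineno: int, path) -> RepeatFeature:
    if len(fields) < 4:
        raise ValueError(f"{path}:{lineno}: repeat BED needs a name column")
    start, end = int(fields[1]), int(fields[2])
    if end <= start:
        raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
    parts = fields[3].split("|")
    if len(parts) < 2:
        raise ValueError(
            f"{path}:{lineno}: repeat BED name must be rep_name|rep_class|rep_family"
        )
    strand = fields[5] if len(fields) >= 6 else "?"
    return RepeatFeature(
        chrom=fields[0],
        start=start,
        end=end,
        strand=strand,
        rep_name=parts[0],
        rep_class=parts[1],
        rep_family=parts[2] if len(parts) > 2 else "",
    )


def read_repeats(
    path: str | Path,
    dialect: str,
    genome: GenomeMap | None = None,
) -> list[RepeatFeature]:
    """Read repeat annotations; ``dialect`` is rmsk_out, ucsc_rmsk or bed."""
    if dialect not in ("rmsk_out", "ucsc_rmsk", "bed"):
        raise ValueError(f"unknown repeat dialect {dialect!r}")
    features: list[RepeatFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if dialect == "rmsk_out" and (
                lineno <= 3 and (stripped.startswith(("SW", "score")) or not stripped[0].isdigit())
            ):
                continue  # the three standard header lines
            if dialect == "ucsc_rmsk" and stripped.startswith("#"):
                continue
            if dialect == "bed" and stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if dialect == "ucsc_rmsk" else stripped.split()
            try:
                if dialect == "rmsk_out":
                    feat = _parse_rmsk_out_line(fields, lineno, path)
                elif dialect == "ucsc_rmsk":
                    feat = _parse_ucsc_rmsk_line(fields, lineno, path)
                else:
                    feat = _parse_bed_repeat_line(fields, lineno, path)
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and str(exc).startswith(str(path)):
                    raise
                raise ValueError(f"{path}:{lineno}: unparseable line ({exc})") from None
            features.append(feat)
    _validate_against_genome(features, genome, "repeat")
    features.sort(key=lambda f: (f.chrom, f.start, f.end))
    return features


_UCSC_HEADER = (
    "#bin\tswScore\tmilliDiv\tmilliDel\tmilliIns\tgenoName\tgenoStart\tgenoEnd\t"
    "genoLeft\tstrand\trepName\trepClass\trepFamily\trepStart\trepEnd\trepLeft\tid\n"
)


def write_repeats_ucsc(
    features: Iterable[RepeatFeature], path: str | Path, genome: GenomeMap | None = None
) -> None:
    """Write repeats as a UCSC ``rmsk``-style TSV (round-trips through
    :func:`read_repeats` with dialect ``ucsc_rmsk``)."""
    with open(path, "wt", encoding="ascii") as fh:
        fh.write(_UCSC_HEADER)
        for i, f in enumerate(features):
            left = (genome[f.chrom] - f.end) if genome is not None else 0
            div = f.divergence if f.divergence is not None else 0
            fh.write(
                f"0\t0\t{div}\t0\t0\t{f.chrom}\t{f.start}\t{f.end}\t{-left}\t"
                f"{f.strand}\t{f.rep_name}\t{f.rep_class}\t{f.rep_family}\t0\t0\t0\t{i}\n"
            )


def read_bed_track(path: str | Path) -> list[BedRecord]:
    """Read a BED3/BED6 track; intervals validated and sorted."""
    records: list[BedRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) == 1:
                fields = stripped.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start > end:
                raise ValueError(f"{path}:{lineno}: invalid coordinates {start}-{end}")
            records.append(
                BedRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) >= 4 else None,
                    score=float(fields[4]) if len(fields) >= 5 else None,
                    strand=fields[5] if len(fields) >= 6 else None,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_bed_track(records: Iterable[BedRecord | Interval], path: str | Path) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for r in records:
            name = getattr(r, "name", None)
            score = getattr(r, "score", None)
            strand = getattr(r, "strand", None)
            fields = [r.chrom, str(r.start), str(r.end)]
            if name is not None:
                fields.append(name)
                if score is not None:
                    fields.append(f"{score:g}")
                    if strand is not None:
                        fields.append(strand)
            fh.write("\t".join(fields) + "\n")


def read_genes(path: str | Path, genome: GenomeMap | None = None) -> list[GeneFeature]:
    """Read gene annotations from BED4+ (name column required)."""
    genes: list[GeneFeature] = []
    for r in read_bed_track(path):
        if r.name is None:
            raise ValueError(f"{path}: gene records need a name column")
        if r.end == r.start:
            raise ValueError(f"{path}: zero-length gene {r.name}")
        genes.append(
            GeneFeature(
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                strand=r.strand or "?",
                name=r.name,
            )
        )
    _validate_against_genome(genes, genome, "gene")
    return genes


@dataclass
class LADCollection:
    """Per-cell-type lamina-associated-domain tracks."""

    tracks: dict[str, IntervalSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("LADCollection needs at least one cell type")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.tracks)

    @classmethod
    def from_bed_files(
        cls, paths: Mapping[str, str | Path], genome: GenomeMap | None = None
    ) -> "LADCollection":
        tracks = {}
        for label, path in paths.items():
            records = read_bed_track(path)
            _validate_against_genome(
                [r for r in records if r.end > r.start], genome, f"LAD ({label})"
            )
            tracks[label] = IntervalSet.from_tuples(
                (r.chrom, r.start, r.end) for r in records if r.end > r.start
            )
        return cls(tracks)


def region_id(region) -> str:
    return f"{region.chrom}:{region.start}-{region.end}"


def write_region_report(regions, path_bed: str | Path, path_tsv: str | Path) -> None:
    """Write called array regions as BED6 (score = round(density*1000)) and
    as a TSV with context / gene / LAD annotations."""
    import math

    with open(path_bed, "wt", encoding="ascii") as fh:
        for r in regions:
            density = getattr(r, "density", float("nan"))
            score = 0 if math.isnan(density) else int(round(density * 1000))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{region_id(r)}\t{score}\t.\n"
            )
    header = (
        "chrom\tstart\tend\tlength_bp\tdensity\tn_windows\tcontext\t"
        "contained_genes\tlad_status\n"
    )
    with open(path_tsv, "wt", encoding="ascii") as fh:
        fh.write(header)
        for r in regions:
            density = getattr(r, "density", float("nan"))
            context = getattr(r, "context", None)
            lad = getattr(r, "lad_status", None)
            genes = getattr(r, "contained_genes", ()) or ()
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.end - r.start}\t"
                f"{density:.6f}\t{getattr(r, 'n_windows', 0)}\t"
                f"{getattr(context, 'name', context) or 'NA'}\t"
                f"{','.join(genes) or 'NA'}\t{getattr(lad, 'name', lad) or 'NA'}\n"
            )
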