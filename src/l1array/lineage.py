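"""Evolutionary-lineage stratification of repeat elements.

L1 subfamilies amplified in different clades; the subfamily name therefore
dates an element to the lineage in which it spread (Eutherian-wide, then
Rodent, Muridae and finally Mus-specific subfamilies).  A
:class:`LineageMap` holds ordered name-prefix rules mapping subfamily
names to lineage labels; the bundled default covers the common mouse L1
subfamily prefixes and can be replaced by a two-column TSV for other
genomes.  Stratification counts elements genome-wide and inside/outside
called arrays - membership is decided by the element midpoint, so an
element straddling a boundary is counted exactly once.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass
from pathlib import Path

from .intervals import IntervalSet
from .io import RepeatFeature
from .scan import l1_family_filter

__all__ = ["LineageMap", "LineageTable", "lineage_stratify", "DEFAULT_MOUSE_L1_RULES"]

UNASSIGNED = "unassigned"

# first matching prefix wins; ordered young -> old mouse L1 subfamilies
DEFAULT_MOUSE_L1_RULES: tuple[tuple[str, str], ...] = (
    ("L1Md_", "Mus"),
    ("Lx", "Muridae"),
    ("L1_Mur", "Rodent"),
    ("L1_Mus", "Rodent"),
    ("L1MA", "Eutherian"),
    ("L1MB", "Eutherian"),
    ("L1MC", "Eutherian"),
    ("L1MD", "Eutherian"),
    ("L1ME", "Eutherian"),
    ("L1M", "Eutherian"),
)

DEFAULT_LINEAGES: tuple[str, ...] = ("Eutherian", "Rodent", "Muridae", "Mus")


@dataclass(frozen=True)
class LineageMap:
    """Ordered (prefix, label) rules; unmapped names -> ``unassigned``."""

    rules: tuple[tuple[str, str], ...]
    lineages: tuple[str, ...]

    def __post_init__(self) -> None:
        declared = set(self.lineages)
        for prefix, label in self.rules:
            if label not in declared:
                raise ValueError(f"rule {prefix!r} maps to undeclared label {label!r}")

    @classmethod
    def default_mouse(cls) -> "LineageMap":
        return cls(rules=DEFAULT_MOUSE_L1_RULES, lineages=DEFAULT_LINEAGES)

    @classmethod
    def from_tsv(cls, path: str | Path, lineages: Sequence[str] | None = None) -> "LineageMap":
        """Two columns: name prefix, lineage label.  Rule order = file order;
        label order (for ratios) = first appearance unless given."""
        rules: list[tuple[str, str]] = []
        seen: list[str] = []
        with open(path, "rt", encoding="ascii") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected prefix and label")
                rules.append((fields[0], fields[1]))
                if fields[1] not in seen:
                    seen.append(fields[1])
        if not rules:
            raise ValueError(f"{path}: no lineage rules")
        return cls(rules=tuple(rules), lineages=tuple(lineages or seen))

    def assign(self, rep_name: str) -> str:
        for prefix, label in self.rules:
            if rep_name.startswith(prefix):
                return label
        return UNASSIGNED


@dataclass(frozen=True)
class LineageTable:
    """Per-lineage element counts genome-wide and inside/outside arrays.

    Ratios are normalized to the first declared lineage.  Conservation
    holds exactly: within + outside = genomewide for every lineage.
    """

    lineages: tuple[str, ...]
    genomewide: dict[str, int]
    within_arrays: dict[str, int]
    outside_arrays: dict[str, int]
    unassigned_genomewide: int
    unassigned_within: int

    def ratios_genomewide(self) -> dict[str, float]:
        return self._ratios(self.genomewide)

    def ratios_within(self) -> dict[str, float]:
        return self._ratios(self.within_arrays)

    def _ratios(self, counts: dict[str, int]) -> dict[str, float]:
        base = counts[self.lineages[0]]
        if base == 0:
            return {lin: float("nan") for lin in self.lineages}
        return {lin: counts[lin] / base for lin in self.lineages}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt", encoding="ascii") as fh:
            fh.write("lineage\tgenomewide\twithin_arrays\toutside_arrays\n")
            for lin in self.lineages:
                fh.write(
                    f"{lin}\t{self.genomewide[lin]}\t{self.within_arrays[lin]}\t"
                    f"{self.outside_arrays[lin]}\n"
                )
            fh.write(
                f"{UNASSIGNED}\t{self.unassigned_genomewide}\t{self.unassigned_within}\t"
                f"{self.unassigned_genomewide - self.unassigned_within}\n"
            )


def lineage_stratify(
    repeats: Sequence[RepeatFeature],
    regions: Sequence,
    lineage_map: LineageMap,
    element_filter: Callable[[RepeatFeature], bool] = l1_family_filter,
) -> LineageTable:
    """Count filtered elements per lineage, split by array membership."""
    region_set = IntervalSet.from_tuples(
        (r.chrom, r.start, r.end) for r in regions
    ) if regions else IntervalSet()
    genomewide = {lin: 0 for lin in lineage_map.lineages}
    within = {lin: 0 for lin in lineage_map.lineages}
    un_total = un_within = 0
    for f in repeats:
        if not element_filter(f):
            continue
        label = f.lineage or lineage_map.assign(f.rep_name)
        inside = bool(region_set.contains_points(f.chrom, f.midpoint)[0])
        if label in genomewide:
            genomewide[label] += 1
            if inside:
                within[label] += 1
        else:
            un_total += 1
            if inside:
                un_within += 1
    outside = {lin: genomewide[lin] - within[lin] for lin in lineage_map.lineages}
    return LineageTable(
        lineages=lineage_map.lineages,
        genomewide=genomewide,
        within_arrays=within,
        outside_arrays=outside,
        unassigned_genomewide=un_total,
        unassigned_within=un_within,
    )
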