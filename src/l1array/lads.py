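"""Lamina-associated-domain overlap classification of called arrays.

A region counts as lamina-associated in a cell type when it overlaps that
cell type's LADs by at least ``min_overlap`` bases (10 kb by default).
LAD fragments within one cell type are unioned before measuring, so
adjacent fragments jointly satisfy the rule - the criterion is total
lamina contact, not contact with a single annotated fragment.  A region
meeting the rule in every assayed cell type is a constitutive LAD (cLAD);
in at least one but not all, facultative (fLAD); otherwise none.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from enum import Enum

from .io import LADCollection, region_id

__all__ = ["LADStatus", "LADCallRecord", "LADSummary", "lad_overlap"]


class LADStatus(Enum):
    CONSTITUTIVE = "CONSTITUTIVE"
    FACULTATIVE = "FACULTATIVE"
    NONE = "NONE"


@dataclass(frozen=True)
class LADCallRecord:
    region_id: str
    overlapping_cell_types: tuple[str, ...]
    status: LADStatus


@dataclass(frozen=True)
class LADSummary:
    n_regions: int
    n_any: int
    n_constitutive: int
    n_facultative: int
    n_none: int


def lad_overlap(
    regions: Sequence,
    lads: LADCollection,
    min_overlap: int = 10_000,
) -> tuple[list[LADCallRecord], LADSummary]:
    """Classify each region's LAD overlap across cell types."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not lads.tracks:
        raise ValueError("empty LAD collection")
    records: list[LADCallRecord] = []
    n_const = n_fac = n_none = 0
    n_types = len(lads.tracks)
    for r in regions:
        hit_types = []
        for label, track in lads.tracks.items():
            ov = int(track.covered_in(r.chrom, r.start, r.end)[0])
            if ov >= min_overlap:
                hit_types.append(label)
        if len(hit_types) == n_types:
            status = LADStatus.CONSTITUTIVE
            n_const += 1
        elif hit_types:
            status = LADStatus.FACULTATIVE
            n_fac += 1
        else:
            status = LADStatus.NONE
            n_none += 1
        records.append(LADCallRecord(region_id(r), tuple(hit_types), status))
    summary = LADSummary(
        n_regions=len(records),
        n_any=n_const + n_fac,
        n_constitutive=n_const,
        n_facultative=n_fac,
        n_none=n_none,
    )
    return records, summary
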