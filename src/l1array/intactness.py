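"""Simplified full-length LINE-1 intactness assessment from sequence.

A retrotransposition-competent L1 is full length (~6 kb in mouse), carries
two long open reading frames - ORF1 (an RNA-binding protein, ~300+ aa)
near the 5' end and ORF2 (endonuclease/reverse transcriptase, ~1200+ aa)
downstream of it - and ends in a functional AATAAA polyadenylation signal.
This module checks exactly those four properties and reports a defect
string for every failed one.  It is deliberately a simplified classifier:
frameshifts are detected only through their consequence (loss of a
qualifying ORF), not by alignment to a consensus, and 5' promoter/monomer
architecture is not examined.  Inputs are sense-oriented element
sequences; soft-masked (lowercase) bases are uppercased on input.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "ElementSpec",
    "ORFRecord",
    "IntactnessReport",
    "find_orfs",
    "assess_element",
    "assess_fasta",
    "write_intactness_tsv",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class ElementSpec:
    """Thresholds of the intactness classifier.

    Defaults sit near the canonical mouse L1: ~6 kb element, ORF1 >= 300
    codons beginning in the 5' 45 % of the element, ORF2 >= 1200 codons
    downstream, and an AATAAA hexamer within the final 60 bp.
    """

    expected_length: int = 6_000
    full_length_fraction: float = 0.95
    orf1_min_aa: int = 300
    orf2_min_aa: int = 1_200
    orf1_search_window: float = 0.45
    polya_signal: str = "AATAAA"
    polya_window: int = 60

    def __post_init__(self) -> None:
        if min(self.expected_length, self.orf1_min_aa, self.orf2_min_aa,
               self.polya_window) <= 0 or self.full_length_fraction <= 0:
            raise ValueError("all thresholds must be positive")
        if self.orf1_min_aa >= self.orf2_min_aa:
            raise ValueError("orf1_min_aa must be < orf2_min_aa")


@dataclass(frozen=True, slots=True)
class ORFRecord:
    """One open reading frame in a forward frame.

    ``end`` is half-open and includes the terminating codon;
    ``length_aa`` counts codons from ATG up to (not including) it.
    ``stop_codon`` is False when the scan ended at the sequence end
    (open-ended) or at a codon containing an ambiguous base.
    """

    start: int
    end: int
    frame: int
    length_aa: int
    stop_codon: bool = True
    note: str | None = None


def find_orfs(seq: str, min_aa: int = 1) -> list[ORFRecord]:
    """All ORFs of >= ``min_aa`` codons in the three forward frames.

    An ORF opens at an ATG and runs to the next in-frame stop; nested
    starts sharing a stop are collapsed to the longest (earliest ATG).  A
    codon containing N terminates the ORF with note ``ambiguous base``; an
    ORF reaching the sequence end without a stop is flagged open-ended.
    """
    seq = seq.upper()
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    orfs: list[ORFRecord] = []
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS or "N" in codon:
                length_aa = (pos - open_start) // 3
                if length_aa >= min_aa:
                    orfs.append(
                        ORFRecord(
                            start=open_start,
                            end=pos + 3,
                            frame=frame,
                            length_aa=length_aa,
                            stop_codon=codon in STOP_CODONS,
                            note=None if codon in STOP_CODONS else "ambiguous base",
                        )
                    )
                open_start = None
            pos += 3
        if open_start is not None:
            end = open_start + 3 * ((n - open_start) // 3)
            length_aa = (end - open_start) // 3
            if length_aa >= min_aa:
                orfs.append(
                    ORFRecord(
                        start=open_start,
                        end=end,
                        frame=frame,
                        length_aa=length_aa,
                        stop_codon=False,
                        note="open-ended",
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


@dataclass(frozen=True)
class IntactnessReport:
    element_id: str
    length: int
    is_full_length: bool
    orf1_ok: bool
    orf2_ok: bool
    polya_ok: bool
    defects: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_intact(self) -> bool:
        return self.is_full_length and self.orf1_ok and self.orf2_ok and self.polya_ok


def assess_element(
    seq: str, spec: ElementSpec = ElementSpec(), element_id: str = ""
) -> IntactnessReport:
    """Assess one sense-oriented element sequence against ``spec``.

    Qualifying ORFs must terminate at a genuine stop codon: an open-ended
    or N-terminated reading frame is not an intact ORF.
    """
    seq = seq.upper()
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    n = len(seq)
    defects: list[str] = []

    min_len = spec.full_length_fraction * spec.expected_length
    is_full = n >= min_len
    if not is_full:
        defects.append(
            f"length {n} below full-length threshold "
            f"({spec.full_length_fraction:g} x {spec.expected_length})"
        )

    # ORF2 anchors the assessment: it is the defining long ORF of an L1 and,
    # at ~1200+ codons in a ~6 kb element, necessarily begins within the 5'
    # half - so ORF1 is required to be a *distinct* long ORF upstream of it.
    orfs = [o for o in find_orfs(seq, min_aa=1) if o.stop_codon]
    window_nt = spec.orf1_search_window * n
    orf2 = max(
        (o for o in orfs if o.length_aa >= spec.orf2_min_aa),
        key=lambda o: (o.length_aa, -o.start),
        default=None,
    )
    orf2_ok = orf2 is not None
    if not orf2_ok:
        defects.append(
            f"no intact ORF2 (>= {spec.orf2_min_aa} aa) "
            "(gap, frameshift, or premature stop in the ORF2 region)"
        )

    orf1_pool = [
        o for o in orfs if o.length_aa >= spec.orf1_min_aa and o.start <= window_nt
    ]
    if orf2 is not None:
        orf1_pool = [o for o in orf1_pool if o.start < orf2.start]
    orf1 = max(orf1_pool, key=lambda o: (o.length_aa, -o.start), default=None)
    if orf1 is None:
        defects.append(
            f"no intact ORF1 (>= {spec.orf1_min_aa} aa) starting within the "
            f"leading {spec.orf1_search_window:g} of the element"
            + (" upstream of ORF2" if orf2 is not None else "")
        )

    tail = seq[-spec.polya_window :]
    polya_ok = spec.polya_signal in tail
    if not polya_ok:
        defects.append(
            f"no {spec.polya_signal} poly(A) signal in the final "
            f"{spec.polya_window} bp"
        )

    return IntactnessReport(
        element_id=element_id,
        length=n,
        is_full_length=is_full,
        orf1_ok=orf1 is not None,
        orf2_ok=orf2_ok,
        polya_ok=polya_ok,
        defects=tuple(defects),
    )


def assess_fasta(
    path: str | Path, spec: ElementSpec = ElementSpec()
) -> list[IntactnessReport]:
    """Assess every record of a FASTA file (header = element id)."""
    return [
        assess_element(str(rec.seq), spec, element_id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_intactness_tsv(reports: Sequence[IntactnessReport], path: str | Path) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        fh.write(
            "id\tlength\tis_full_length\torf1_ok\torf2_ok\tpolya_ok\tis_intact\tdefects\n"
        )
        for r in reports:
            fh.write(
                f"{r.element_id}\t{r.length}\t{int(r.is_full_length)}\t{int(r.orf1_ok)}\t"
                f"{int(r.orf2_ok)}\t{int(r.polya_ok)}\t{int(r.is_intact)}\t"
                f"{';'.join(r.defects) or 'none'}\n"
            )
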