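"""Exact interval-set arithmetic and seeded random region placement.

All coordinates are 0-based, half-open (BED convention).  An
:class:`IntervalSet` stores, per chromosome, a sorted array of disjoint
intervals in which book-ended runs have been merged, so that its total
length equals the number of distinct covered bases.  Queries (coverage
inside a window, intersection length, point membership) are answered from
prefix sums in O(log n) per query.

Random region placement follows the shuffle idiom used by genome-interval
tools: for each draw the chromosome is chosen with probability proportional
to the number of valid start positions ``max(0, chrom_len - length + 1)``
and the start is uniform among them.  A single numpy ``default_rng(seed)``
drives every draw; identical inputs and seed give bitwise identical output.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "Interval",
    "IntervalSet",
    "union_intervals",
    "intersect_length",
    "coverage_fraction",
    "sample_random_regions",
]


@dataclass(frozen=True, slots=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_pairs(pairs: np.ndarray) -> np.ndarray:
    """Merge a (n, 2) array of [start, end) pairs; book-ended runs coalesce."""
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    starts = pairs[order, 0]
    ends = np.maximum.accumulate(pairs[order, 1])
    # a new run begins where the start exceeds the running max end (strict:
    # touching intervals share a boundary base-gap of zero and are merged)
    new_run = np.empty(len(starts), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > ends[:-1]
    run_id = np.cumsum(new_run) - 1
    n_runs = run_id[-1] + 1
    merged = np.empty((n_runs, 2), dtype=np.int64)
    merged[:, 0] = starts[new_run]
    last = np.flatnonzero(np.append(new_run[1:], True))
    merged[:, 1] = ends[last]
    return merged


class IntervalSet:
    """Per-chromosome sorted, disjoint intervals."""

    __slots__ = ("_data", "_cum")

    def __init__(self, data: Mapping[str, np.ndarray] | None = None) -> None:
        # internal constructor: `data` is assumed normalized (sorted, disjoint)
        self._data: dict[str, np.ndarray] = dict(data or {})
        self._cum: dict[str, np.ndarray] = {
            chrom: np.concatenate(([0], np.cumsum(arr[:, 1] - arr[:, 0])))
            for chrom, arr in self._data.items()
        }

    # -- construction --------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval]) -> "IntervalSet":
        return cls.from_tuples((iv.chrom, iv.start, iv.end) for iv in intervals)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if end <= start or start < 0:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        data = {
            chrom: _merge_pairs(np.asarray(pairs, dtype=np.int64))
            for chrom, pairs in per_chrom.items()
        }
        return cls(data)

    # -- basic accessors -----------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._data)

    def arrays(self, chrom: str) -> np.ndarray:
        """The (n, 2) [start, end) array for ``chrom`` (empty if absent)."""
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def n_intervals(self) -> int:
        return sum(len(a) for a in self._data.values())

    def total_length(self) -> int:
        return int(sum(self._cum[c][-1] for c in self._data))

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self._data:
            for start, end in self._data[chrom]:
                yield Interval(chrom, int(start), int(end))

    def __bool__(self) -> bool:
        return self.n_intervals() > 0

    # -- queries -------------------------------------------------------

    def covered_in(self, chrom: str, starts, ends) -> np.ndarray:
        """Covered bases of this set inside each query ``[start, end)``."""
        qs = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        arr = self._data.get(chrom)
        out = np.zeros(len(qs), dtype=np.int64)
        if arr is None or len(arr) == 0:
            return out
        s, e = arr[:, 0], arr[:, 1]
        cum = self._cum[chrom]
        i = np.searchsorted(e, qs, side="right")
        j = np.searchsorted(s, qe, side="left")
        valid = i < j
        if not valid.any():
            return out
        iv = i[valid]
        jv = j[valid]
        total = cum[jv] - cum[iv]
        left_clip = np.maximum(0, qs[valid] - s[iv])
        right_clip = np.maximum(0, e[jv - 1] - qe[valid])
        out[valid] = total - left_clip - right_clip
        return out

    def overlaps(self, chrom: str, starts, ends) -> np.ndarray:
        """Boolean: does each query overlap the set by >= 1 bp."""
        return self.covered_in(chrom, starts, ends) > 0

    def contains_points(self, chrom: str, positions) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        arr = self._data.get(chrom)
        if arr is None or len(arr) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
        ok = idx >= 0
        safe = np.where(ok, idx, 0)
        return ok & (pos < arr[safe, 1])

    def intersect_length(self, other: "IntervalSet") -> int:
        total = 0
        for chrom, arr in other._data.items():
            if chrom in self._data and len(arr):
                total += int(self.covered_in(chrom, arr[:, 0], arr[:, 1]).sum())
        return total


# -- module-level operations -------------------------------------------


def union_intervals(intervals: Iterable[Interval]) -> IntervalSet:
    """Union of arbitrary intervals: each base counted once."""
    return IntervalSet.from_intervals(intervals)


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    """Number of bases covered by both sets (symmetric)."""
    return a.intersect_length(b)


def coverage_fraction(features: IntervalSet, window: Interval) -> float:
    """Fraction of ``window`` covered by ``features``."""
    if window.length <= 0:  # Interval forbids this, but guard explicitly
        raise ValueError("zero-length window")
    covered = features.covered_in(window.chrom, window.start, window.end)[0]
    return float(covered) / window.length


def sample_random_regions(
    genome,
    lengths: Sequence[int],
    n_total: int,
    seed: int,
    exclude: IntervalSet | None = None,
    max_tries: int = 1000,
) -> list[Interval]:
    """Draw ``n_total`` random regions from ``genome`` (a GenomeMap or
    mapping chrom -> length).

    Draw ``i`` uses ``lengths[i % len(lengths)]``.  Chromosomes are chosen
    with probability proportional to the number of valid start positions
    for that draw's length; starts are uniform.  Draws are independent and
    may overlap one another.  With ``exclude`` set, draws overlapping the
    excluded set are rejected and redrawn (off by default).
    """
    entries = list(genome.items())
    if not entries:
        raise ValueError("empty genome")
    names = [c for c, _ in entries]
    sizes = np.asarray([l for _, l in entries], dtype=np.int64)
    lens = [int(l) for l in lengths]
    if not lens:
        raise ValueError("no lengths given")
    for l in lens:
        if l <= 0:
            raise ValueError(f"non-positive region length {l}")
        if l > sizes.max():
            raise ValueError(f"length {l} exceeds every chromosome")

    rng = np.random.default_rng(seed)
    # per unique length: cumulative chromosome weights
    cum_by_len: dict[int, np.ndarray] = {}
    for l in set(lens):
        w = np.maximum(0, sizes - l + 1).astype(np.float64)
        cum_by_len[l] = np.cumsum(w / w.sum())

    out: list[Interval] = []
    for i in range(n_total):
        l = lens[i % len(lens)]
        cum = cum_by_len[l]
        for _ in range(max_tries):
            ci = int(np.searchsorted(cum, rng.random(), side="right"))
            ci = min(ci, len(names) - 1)
            n_starts = int(sizes[ci]) - l + 1
            if n_starts <= 0:  # unreachable given weighting, defensive
                continue
            start = int(rng.integers(0, n_starts))
            if exclude is not None and bool(
                exclude.overlaps(names[ci], start, start + l)[0]
            ):
                continue
            out.append(Interval(names[ci], start, start + l))
            break
        else:
            raise RuntimeError(
                f"could not place a region of length {l} outside the excluded set"
            )
    return out
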