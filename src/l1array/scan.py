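"""Sliding-window repeat-coverage scanning and dense-array calling.

The scan measures, for running windows of width ``window`` advanced by
``step`` along each chromosome, the fraction of bases covered by the union
of repeats passing a class filter (LINEs by default).  Windows whose
fraction strictly exceeds ``min_density`` qualify; overlapping or
book-ended qualifying windows are merged and merged spans at least
``min_length`` long are reported as dense arrays.  The genome-wide defaults
(100-kb windows, 10-kb steps, >70 % LINE, >=100 kb) call the large L1
arrays that in the mouse genome number in the tens; the ``imprinted``
preset (50 kb / 10 kb / >40 % / >=50 kb) targets the weaker enrichment
around imprinted domains.

Boundary refinement: the raw union span of qualifying windows overhangs a
dense array by up to ``window * (1 - min_density)`` on each side, because
a window can qualify while only partly inside the array.  When the repeat
annotations are supplied to :func:`call_arrays`, each merged span is
trimmed at step-bin resolution by a two-component classification of every
bin as array-like or background-like.  Each bin contributes two signals: a
Gaussian likelihood on its coverage fraction (the two component means are
plug-in estimates - the median bin fraction inside span interiors and the
median sub-threshold window fraction - with a fixed scale of 0.15) and a
Poisson likelihood on its count of annotated element starts (dense arrays
consist of many stacked fragments, so the start rate separates the two
regimes even where coverage fluctuates).  Bins are trimmed from each span
edge until two consecutive bins classify as array-like, which localizes
boundaries to within one step of the underlying density change while a
lone dense clump in the background cannot halt the trim.  Without
annotations the raw union span is returned and the density field is NaN.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .intervals import Interval, IntervalSet
from .io import GenomeMap, RepeatFeature

__all__ = [
    "ScanParams",
    "WindowRecord",
    "ArrayRegion",
    "CompositionSummary",
    "line_class_filter",
    "l1_family_filter",
    "window_scan",
    "call_arrays",
    "region_composition",
]


def line_class_filter(feature: RepeatFeature) -> bool:
    return feature.rep_class == "LINE"


def l1_family_filter(feature: RepeatFeature) -> bool:
    return feature.rep_family.startswith("L1")


_PRESETS = {
    "line_array": dict(window=100_000, step=10_000, min_density=0.70, min_length=100_000),
    "imprinted": dict(window=50_000, step=10_000, min_density=0.40, min_length=50_000),
}


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the density scan.

    window
        Running window width W in bp.
    step
        Step s between window starts, 0 < s <= W.
    min_density
        Strict qualification threshold d on the window coverage fraction.
    min_length
        Minimum merged-span length L (>= window).
    class_filter
        Predicate selecting which repeats count toward coverage.
    """

    window: int = 100_000
    step: int = 10_000
    min_density: float = 0.70
    min_length: int = 100_000
    class_filter: Callable[[RepeatFeature], bool] = line_class_filter

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")
        if not (0 < self.min_density <= 1):
            raise ValueError("require 0 < min_density <= 1")
        if self.min_length < self.window:
            raise ValueError("require min_length >= window")

    @classmethod
    def preset(cls, name: str, **overrides) -> "ScanParams":
        if name not in _PRESETS:
            raise ValueError(f"unknown preset {name!r} (have {sorted(_PRESETS)})")
        kwargs = dict(_PRESETS[name])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True, slots=True)
class WindowRecord:
    chrom: str
    start: int
    end: int
    covered_bp: int
    fraction: float


@dataclass
class ArrayRegion:
    """A called dense-repeat region."""

    chrom: str
    start: int
    end: int
    density: float = float("nan")
    n_windows: int = 0
    context: object | None = None
    lad_status: object | None = None
    contained_genes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


def filtered_union(
    repeats: Iterable[RepeatFeature], class_filter: Callable[[RepeatFeature], bool]
) -> IntervalSet:
    """Union of the repeats passing the class filter."""
    return IntervalSet.from_tuples(
        (f.chrom, f.start, f.end) for f in repeats if class_filter(f)
    )


def window_scan(
    repeats: Sequence[RepeatFeature],
    genome: GenomeMap,
    params: ScanParams,
) -> list[WindowRecord]:
    """Coverage fraction of class-filtered repeats in running windows.

    Windows start at 0, s, 2s, ... per chromosome; only complete windows
    (start + W <= chromosome length) are emitted so every fraction shares
    the denominator W.  Chromosomes shorter than W yield no windows.
    """
    cov = filtered_union(repeats, params.class_filter)
    W, s = params.window, params.step
    out: list[WindowRecord] = []
    for chrom, length in genome.items():
        if length < W:
            continue
        starts = np.arange(0, length - W + 1, s, dtype=np.int64)
        covered = cov.covered_in(chrom, starts, starts + W)
        for st, cv in zip(starts.tolist(), covered.tolist()):
            out.append(WindowRecord(chrom, st, st + W, cv, cv / W))
    return out


def _merge_qualifying(windows: list[WindowRecord]) -> list[tuple[str, int, int, int]]:
    """Merge overlapping/book-ended qualifying windows -> (chrom, S, E, n)."""
    spans: list[tuple[str, int, int, int]] = []
    cur = None
    for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
        if cur is not None and w.chrom == cur[0] and w.start <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], w.end), cur[3] + 1)
        else:
            if cur is not None:
                spans.append(cur)
            cur = (w.chrom, w.start, w.end, 1)
    if cur is not None:
        spans.append(cur)
    return spans


# fixed scale of the coverage-fraction likelihood in boundary refinement;
# chosen wide enough that the fragment-count channel can overrule a lone
# coverage fluctuation (see module docstring)
_TRIM_COV_SD = 0.15


@dataclass(frozen=True)
class _TrimModel:
    p0: float  # background bin coverage fraction
    p1: float  # array bin coverage fraction
    m0: float  # background element starts per full step bin
    m1: float  # array element starts per full step bin

    def llr(self, frac: np.ndarray, counts: np.ndarray, widths: np.ndarray) -> np.ndarray:
        cov_part = ((frac - self.p0) ** 2 - (frac - self.p1) ** 2) / (
            2 * _TRIM_COV_SD**2
        )
        cnt_part = poisson.logpmf(
            counts, np.maximum(self.m1 * widths, 1e-9)
        ) - poisson.logpmf(counts, np.maximum(self.m0 * widths, 1e-9))
        return cov_part + cnt_part


def _span_bins(chrom, start, end, cov, starts_by_chrom, step):
    edges = np.arange(start, end, step, dtype=np.int64)
    ends = np.minimum(edges + step, end)
    frac = cov.covered_in(chrom, edges, ends) / (ends - edges)
    st = starts_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
    counts = np.searchsorted(st, ends) - np.searchsorted(st, edges)
    widths = (ends - edges) / step
    return edges, ends, frac, counts, widths


def _fit_trim_model(spans, cov, starts_by_chrom, windows, params) -> _TrimModel:
    """Plug-in two-component estimates from span interiors vs background."""
    step = params.step
    interior_frac: list[float] = []
    interior_cnt: list[float] = []
    span_bp = 0
    n_in = 0
    for chrom, start, end, _ in spans:
        _, _, frac, counts, _ = _span_bins(
            chrom, start, end, cov, starts_by_chrom, step
        )
        inner = slice(3, max(3, len(frac) - 3))
        interior_frac.extend(frac[inner].tolist())
        interior_cnt.extend(counts[inner].tolist())
        span_bp += end - start
        st = starts_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        n_in += int(np.searchsorted(st, end) - np.searchsorted(st, start))
    wf = np.asarray([w.fraction for w in windows], dtype=np.float64)
    low = wf[wf <= 0.5]
    p0 = float(np.median(low)) if len(low) else 0.0
    if len(interior_frac) >= 10:
        p1 = float(np.median(interior_frac))
        m1_obs = float(np.mean(interior_cnt))
    else:
        p1 = min(1.0, params.min_density + 0.15)
        m1_obs = 0.0
    total_starts = sum(len(a) for a in starts_by_chrom.values())
    scanned_bp = sum(
        max((w.end for w in windows if w.chrom == chrom), default=0)
        for chrom in {w.chrom for w in windows}
    )
    bg_bins = max(1.0, (scanned_bp - span_bp) / step)
    m0 = max(0.1, (total_starts - n_in) / bg_bins)
    m1 = max(m0 * 1.5 + 0.5, m1_obs)
    return _TrimModel(p0=p0, p1=max(p1, p0 + 0.05), m0=m0, m1=m1)


def _trim_span(chrom, start, end, cov, starts_by_chrom, model, params):
    """Trim background-classified step bins from each span edge; stopping
    requires two consecutive array-classified bins."""
    edges, ends, frac, counts, widths = _span_bins(
        chrom, start, end, cov, starts_by_chrom, params.step
    )
    ok = model.llr(frac, counts, widths) > 0
    if not ok.any():
        return start, end  # degenerate; keep raw span
    conf_l = ok & np.append(ok[1:], ok[-1:])
    conf_r = ok & np.concatenate(([ok[0]], ok[:-1]))
    if conf_l.any() and conf_r.any():
        first = int(np.argmax(conf_l))
        last = int(len(ok) - 1 - np.argmax(conf_r[::-1]))
    else:  # only isolated array-like bins: fall back to single-bin rule
        first = int(np.argmax(ok))
        last = int(len(ok) - 1 - np.argmax(ok[::-1]))
    return int(edges[first]), int(ends[last])


def call_arrays(
    windows: Sequence[WindowRecord],
    params: ScanParams,
    repeats: Sequence[RepeatFeature] | None = None,
    refine: bool = True,
) -> list[ArrayRegion]:
    """Call dense arrays from a window scan.

    A window qualifies iff ``fraction > min_density`` (strict).  Qualifying
    windows are merged; spans shorter than ``min_length`` are discarded.
    With ``repeats`` supplied, each span is boundary-trimmed at step
    resolution (see module docstring) and its density is recomputed exactly
    over the final span; otherwise the density is NaN and the raw union
    span is reported.
    """
    qualifying = [w for w in windows if w.fraction > params.min_density]
    spans = _merge_qualifying(qualifying)
    cov = filtered_union(repeats, params.class_filter) if repeats is not None else None
    starts_by_chrom: dict[str, np.ndarray] = {}
    model = None
    if cov is not None and refine and spans:
        for f in repeats:
            if params.class_filter(f):
                starts_by_chrom.setdefault(f.chrom, []).append(f.start)
        starts_by_chrom = {
            c: np.asarray(sorted(v), dtype=np.int64)
            for c, v in starts_by_chrom.items()
        }
        model = _fit_trim_model(spans, cov, starts_by_chrom, windows, params)
    regions: list[ArrayRegion] = []
    for chrom, start, end, n in spans:
        if model is not None:
            start, end = _trim_span(
                chrom, start, end, cov, starts_by_chrom, model, params
            )
        if end - start < params.min_length:
            continue
        if cov is not None:
            density = float(cov.covered_in(chrom, start, end)[0]) / (end - start)
        else:
            density = float("nan")
        regions.append(ArrayRegion(chrom, start, end, density=density, n_windows=n))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


@dataclass(frozen=True)
class CompositionSummary:
    """Per-class repeat coverage of one interval.

    ``per_class`` maps rep_class to (covered_bp, fraction); classes absent
    from the annotations report zero via :meth:`fraction_of`.  The total
    interspersed fraction is the union over all classes, so it never
    exceeds 1 and never falls below any single class.
    """

    interval: Interval
    per_class: dict[str, tuple[int, float]]
    total_interspersed_bp: int
    total_interspersed_fraction: float

    def fraction_of(self, rep_class: str) -> float:
        return self.per_class.get(rep_class, (0, 0.0))[1]


def region_composition(
    interval: Interval, repeats: Sequence[RepeatFeature]
) -> CompositionSummary:
    """Repeat composition of ``interval``: per-class and total coverage."""
    if interval.length <= 0:
        raise ValueError("zero-length interval")
    by_class: dict[str, list[RepeatFeature]] = {}
    for f in repeats:
        if f.chrom == interval.chrom and f.start < interval.end and f.end > interval.start:
            by_class.setdefault(f.rep_class, []).append(f)
    per_class: dict[str, tuple[int, float]] = {}
    for cls, feats in sorted(by_class.items()):
        cov = IntervalSet.from_tuples((f.chrom, f.start, f.end) for f in feats)
        bp = int(cov.covered_in(interval.chrom, interval.start, interval.end)[0])
        per_class[cls] = (bp, bp / interval.length)
    all_cov = IntervalSet.from_tuples(
        (f.chrom, f.start, f.end) for feats in by_class.values() for f in feats
    )
    total_bp = (
        int(all_cov.covered_in(interval.chrom, interval.start, interval.end)[0])
        if by_class
        else 0
    )
    return CompositionSummary(
        interval=interval,
        per_class=per_class,
        total_interspersed_bp=total_bp,
        total_interspersed_fraction=total_bp / interval.length,
    )
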