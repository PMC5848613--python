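"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's interval machinery: they
paint per-base boolean masks and count, so they stay independent of the
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from l1array import Interval


def mask_of(intervals, length: int) -> np.ndarray:
    """Per-base boolean coverage mask of a toy chromosome."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        start = iv.start if hasattr(iv, "start") else iv[0]
        end = iv.end if hasattr(iv, "end") else iv[1]
        mask[start:end] = True
    return mask


def random_intervals(rng, n_max: int, chrom_len: int, chrom: str = "chrT"):
    """Up to ``n_max`` random intervals on one toy chromosome."""
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(chrom_len, start + 1 + int(rng.integers(1, 400))) + 1))
        out.append(Interval(chrom, start, min(end, chrom_len)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_927)
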