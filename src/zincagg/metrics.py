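"""Aggregation metrics built on complex compositions.

The central statistic is the connectivity length

    L_c = sum_i sqrt(N_i)

over the complexes i of a frame, N_i the number of molecule units in
complex i (a zinc-bridged dimer counts as one unit).  For a fixed total
M, L_c ranges from sqrt(M) (one complex containing everything) up to M
(all singletons); the smaller the connectivity length, the stronger the
aggregation.  It is not normalised, so values are only comparable
between systems with the same total unit count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ComplexComposition


def _sizes(composition) -> Sequence[int]:
    if isinstance(composition, ComplexComposition):
        return composition.sizes
    return tuple(int(s) for s in composition)


def connectivity_length(composition) -> float:
    """Sum of square roots of complex sizes, at full precision.

    Accepts a ComplexComposition or any iterable of sizes.  Round to two
    decimals only for presentation (`round(lc, 2)`, banker's rounding,
    which matches the printed convention).
    """
    sizes = _sizes(composition)
    if len(sizes) == 0:
        raise ValueError("empty composition has no connectivity length")
    if any(s < 1 for s in sizes):
        raise ValueError("complex sizes must be >= 1")
    return float(sum(math.sqrt(s) for s in sizes))


@dataclass(frozen=True)
class AggregationReport:
    lc: float
    n_units: int
    largest: int
    largest_fraction: float
    size_histogram: dict[int, int]


def aggregation_report(composition) -> AggregationReport:
    """Summary statistics of one composition."""
    sizes = _sizes(composition)
    lc = connectivity_length(sizes)
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    n = sum(sizes)
    largest = max(sizes)
    return AggregationReport(
        lc=lc,
        n_units=n,
        largest=largest,
        largest_fraction=largest / n,
        size_histogram=hist,
    )


def lc_timeseries(compositions: Iterable) -> list[float]:
    """Elementwise connectivity length over a composition series."""
    return [connectivity_length(c) for c in compositions]
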