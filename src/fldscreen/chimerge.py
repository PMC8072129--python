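"""ChiMerge supervised discretisation of a continuous variable.

Bottom-up merging against a binary label: start with one bin per distinct
value, repeatedly merge the adjacent pair of bins whose 2x2 chi-square
independence statistic is smallest (leftmost pair on ties), and stop when
the requested number of bins remains. Low chi-square between neighbouring
bins means their class mix is similar, so merging them loses little
label information.

Intervals are right-closed with unbounded outer edges — ``(-inf, c1],
(c1, c2], ..., (c_{k-1}, +inf)`` — so any finite value, including unseen
extremes in a test set, maps to a bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import FitError, InputError


def chi_square_adjacent(counts) -> float:
    """Chi-square independence statistic for two adjacent bins.

    ``counts`` is a 2x2 array: rows = the two bins, columns = the two
    classes. Cells with zero expected count contribute zero, so a bin
    with no observations (or an empty class) yields statistic 0 and is
    merged first.
    """
    a = np.asarray(counts, dtype=float)
    if a.shape != (2, 2):
        raise InputError("expected a 2x2 count table")
    if np.any(a < 0):
        raise InputError("counts must be non-negative")
    row = a.sum(axis=1, keepdims=True)
    col = a.sum(axis=0, keepdims=True)
    total = a.sum()
    if total == 0:
        return 0.0
    expected = row * col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (a - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


@dataclass(frozen=True)
class BinningScheme:
    """Ordered cut points defining right-closed intervals over the line."""

    cut_points: tuple[float, ...]
    target_bins: int = 5

    def __post_init__(self):
        cuts = np.asarray(self.cut_points, dtype=float)
        if cuts.size and not np.all(np.diff(cuts) > 0):
            raise InputError("cut points must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    def intervals(self) -> list[str]:
        """Human-readable interval labels, e.g. ``(17, 29]``."""
        edges = [-np.inf, *self.cut_points, np.inf]
        out = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            left = "(-inf" if np.isinf(lo) else f"({lo:g}"
            right = "+inf)" if np.isinf(hi) else f"{hi:g}]"
            out.append(f"{left}, {right}")
        return out

    def to_json(self) -> str:
        return json.dumps({"cut_points": list(self.cut_points),
                           "target_bins": self.target_bins})

    @classmethod
    def from_json(cls, text: str) -> "BinningScheme":
        doc = json.loads(text)
        return cls(tuple(doc["cut_points"]), int(doc["target_bins"]))


def assign_bin(scheme: BinningScheme, values) -> np.ndarray:
    """Bin index for each value under the right-closed convention.

    ``value <= c1`` maps to bin 0; ``value > c_last`` maps to the last
    bin. Accepts a scalar or an array; returns int indices of the same
    shape. Non-finite values are rejected.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("cannot bin non-finite values")
    idx = np.searchsorted(np.asarray(scheme.cut_points, dtype=float),
                          arr, side="left")
    return idx if arr.shape else int(idx)


def _pair_stat(top: tuple[int, int], bottom: tuple[int, int]) -> tuple[int, int]:
    """Exact chi-square of a 2x2 integer table as a (num, den) ratio.

    Uses the closed form N(ad - bc)^2 / (R1 R2 C1 C2); a zero margin
    means every positive-expectation term vanishes, i.e. statistic 0.
    Integer arithmetic makes ties exact, so the leftmost-pair rule is
    decided by mathematics rather than floating-point rounding.
    """
    a, b = top
    c, d = bottom
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return (0, 1)
    return ((a + b + c + d) * (a * d - b * c) ** 2, den)


def _less(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] * y[1] < y[0] * x[1]


def fit_chimerge(values, labels, target_bins: int = 5) -> BinningScheme:
    """Fit a ChiMerge binning of ``values`` against binary ``labels``.

    Initialises one bin per distinct value (sorted ascending), then
    greedily merges the adjacent pair with the smallest chi-square
    statistic, the leftmost pair on ties, until ``min(target_bins,
    #distinct values)`` bins remain. Deterministic; depends only on the
    multiset of (value, label) pairs.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels)
    if vals.size == 0:
        raise FitError("cannot fit a binning on empty input")
    if vals.shape != labs.shape:
        raise InputError("values and labels must have the same length")
    if not np.all(np.isfinite(vals)):
        raise InputError("values must be finite")
    if not np.isin(labs, (0, 1)).all():
        raise InputError("labels must be binary 0/1")
    if target_bins < 1:
        raise InputError("target_bins must be >= 1")

    distinct, inverse = np.unique(vals, return_inverse=True)
    grid = np.zeros((distinct.size, 2), dtype=np.int64)
    np.add.at(grid, (inverse, labs.astype(int)), 1)
    counts: list[tuple[int, int]] = [tuple(map(int, row)) for row in grid]
    upper = list(distinct)  # right edge of each current bin

    while len(upper) > target_bins:
        best_i, best = 0, _pair_stat(counts[0], counts[1])
        for i in range(1, len(counts) - 1):
            stat = _pair_stat(counts[i], counts[i + 1])
            if _less(stat, best):  # strict: leftmost minimal pair wins ties
                best_i, best = i, stat
        i = best_i
        counts[i] = (counts[i][0] + counts[i + 1][0],
                     counts[i][1] + counts[i + 1][1])
        del counts[i + 1]
        del upper[i]

    # cut points are the right edges of all bins but the last
    return BinningScheme(tuple(float(u) for u in upper[:-1]),
                         target_bins=target_bins)
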