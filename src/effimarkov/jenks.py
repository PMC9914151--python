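"""Exact Fisher-Jenks natural-breaks classification.

Partitions a set of real values into ``k`` contiguous classes minimizing the
total within-class sum of squared deviations from the class means — the
exact dynamic-programming optimum, not the iterative "Jenks optimization"
heuristic. Class cut points are placed at the midpoints between the
boundary values of adjacent optimal classes, so classification of unseen
values (e.g. spatial-lag averages) is well defined.

Classes follow a left-closed convention: a value belongs to class ``j+1``
when it is >= the j-th cut; the top class is unbounded above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StateBreaks:
    """Ascending cut points defining k = len(cuts) + 1 ordered classes."""

    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(nxt <= prev for prev, nxt in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cuts must be strictly ascending")

    @property
    def k(self) -> int:
        return len(self.cuts) + 1

    def classify(self, values) -> np.ndarray:
        """Map values to 1-based class indices (value == cut goes upward)."""
        return np.searchsorted(self.cuts, np.asarray(values, float),
                               side="right") + 1


def jenks_breaks(values, k: int) -> StateBreaks:
    """Exact Fisher-Jenks optimal k-class breaks of a value set.

    Dynamic program over the sorted values with prefix sums; O(k n^2).
    Ties in the optimum are broken toward the smallest boundary indices
    (the scan keeps the first minimizer), making the result deterministic.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(x)) < k:
        raise ValueError(
            f"need at least {k} distinct values for {k} classes, "
            f"got {len(np.unique(x))}"
        )
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        # within-class sum of squares of x[i:j]
        s = cs[j] - cs[i]
        return cs2[j] - cs2[i] - s * s / (j - i)

    inf = np.inf
    cost = np.full((k + 1, n + 1), inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = inf, -1
            for i in range(c - 1, j):
                if cost[c - 1, i] == inf:
                    continue
                v = cost[c - 1, i] + ssd(i, j)
                if v < best - 1e-12:
                    best, arg = v, i
            cost[c, j], back[c, j] = best, arg

    bounds = []
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        bounds.append(j)
    starts = bounds[::-1][1:]  # first index of classes 2..k
    cuts = tuple((x[b - 1] + x[b]) / 2 for b in starts)
    return StateBreaks(cuts)


def jenks_cost(values, breaks: StateBreaks) -> float:
    """Total within-class sum of squared deviations under given breaks."""
    x = np.asarray(values, float)
    labels = breaks.classify(x)
    return float(sum(
        ((x[labels == c] - x[labels == c].mean()) ** 2).sum()
        for c in np.unique(labels)
    ))
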