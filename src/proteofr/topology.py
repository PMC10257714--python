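"""Bipartite topology metrics: connectance, degrees, NODF nestedness.

A content network is binarized at weight > 0 (no abundance cutoff). NODF
(nestedness metric based on overlap and decreasing fill) asks whether the
links of low-degree rows/columns are subsets of the links of high-degree
ones; in a content network this means specialist taxa expressing a subset
of generalists' functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import TaxonFunctionNetwork
from .errors import ValidationError


@dataclass(frozen=True)
class NestednessResult:
    """NODF on the [0, 1] scale, overall and per axis."""

    nodf: float
    nodf_rows: float
    nodf_cols: float


def connectance(net: TaxonFunctionNetwork) -> float:
    """Realized links over maximal possible links, in [0, 1]."""
    s, f = net.shape
    if s < 1 or f < 1:
        raise ValidationError("connectance needs at least one taxon and one function")
    return float(np.count_nonzero(net.weights)) / (s * f)


def degree_distribution(
    net: TaxonFunctionNetwork, axis: str = "functions"
) -> dict[int, int]:
    """Histogram of unweighted degrees along one axis.

    A taxon's degree is its count of nonzero weights; a function's degree
    is the number of taxa expressing it. Returns {degree: count}.
    """
    if axis not in ("taxa", "functions"):
        raise ValidationError(f"axis must be 'taxa' or 'functions', got {axis!r}")
    b = net.binary()
    degrees = b.sum(axis=1) if axis == "taxa" else b.sum(axis=0)
    values, counts = np.unique(degrees, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def _axis_contributions(b: np.ndarray) -> tuple[float, int]:
    """Sum of paired NODF contributions over row pairs of a binary matrix.

    For rows u, v with fill(u) > fill(v) > 0 the contribution is
    |support(u) & support(v)| / fill(v); pairs with equal fill (the
    decreasing-fill condition) or empty v contribute 0.
    """
    fills = b.sum(axis=1)
    n = b.shape[0]
    overlap = (b.astype(float) @ b.T.astype(float))
    total = 0.0
    for u in range(n):
        for v in range(n):
            if u == v:
                continue
            if fills[u] > fills[v] > 0:
                total += overlap[u, v] / fills[v]
    # each unordered pair counted once: the fill(u) > fill(v) condition
    # already selects a single orientation
    return total, n * (n - 1) // 2


def nodf(net: TaxonFunctionNetwork) -> NestednessResult:
    """Almeida-Neto NODF of the binarized network, on the [0, 1] scale.

    The overall value is the sum of paired contributions over all row
    pairs and all column pairs, divided by the total number of pairs
    S(S-1)/2 + F(F-1)/2.
    """
    s, f = net.shape
    if s < 2 and f < 2:
        raise ValidationError("NODF needs at least two rows or two columns")
    b = net.binary()
    row_sum, row_pairs = _axis_contributions(b)
    col_sum, col_pairs = _axis_contributions(b.T)
    total_pairs = row_pairs + col_pairs
    return NestednessResult(
        nodf=(row_sum + col_sum) / total_pairs if total_pairs else 0.0,
        nodf_rows=row_sum / row_pairs if row_pairs else 0.0,
        nodf_cols=col_sum / col_pairs if col_pairs else 0.0,
    )
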