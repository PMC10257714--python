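"""Functional distances and diversity/redundancy metrics.

For a sample with taxa proportions ``p_i`` and pairwise functional
distances ``d_ij`` between row-normalized functional profiles:

* taxonomic diversity ``TD = 1 - sum_i p_i^2`` (Gini-Simpson);
* functional diversity ``FD = sum_{i != j} d_ij p_i p_j`` (Rao's
  quadratic entropy);
* functional redundancy ``FR = TD - FD = sum_{i != j} (1 - d_ij) p_i p_j``;
* normalized redundancy ``nFR = FR / TD``, the expected functional
  similarity of two randomly drawn distinct members.

Distances are weighted Jaccard distances between the taxon rows of the
content network, computed within the sample: expressed proteomes respond
to the environment, so a pooled cross-sample reference profile would not
represent any one sample.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    AbundanceProfile,
    DiversitySummary,
    FunctionalDistanceMatrix,
    TaxonFunctionNetwork,
)
from .errors import AlignmentError, ValidationError


def weighted_jaccard(net: TaxonFunctionNetwork) -> FunctionalDistanceMatrix:
    """Pairwise weighted Jaccard distances between taxon rows.

    ``d_ij = 1 - sum_a min(w_ia, w_ja) / sum_a max(w_ia, w_ja)``.
    """
    w = net.weights
    s = w.shape[0]
    if s < 1:
        raise ValidationError("network has no taxa")
    row_sums = w.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValidationError("all-zero taxon row; cannot compute distances")
    # sum min(w_i, w_j) and sum max via the identity max = w_i + w_j - min
    d = np.zeros((s, s))
    for i in range(s):
        mins = np.minimum(w[i], w[i:]).sum(axis=1)
        maxs = row_sums[i] + row_sums[i:] - mins
        d[i, i:] = 1.0 - mins / maxs
    d = d + d.T
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return FunctionalDistanceMatrix(list(net.taxa), d)


def taxonomic_diversity(profile: AbundanceProfile) -> float:
    """Gini-Simpson index ``1 - sum p_i^2``."""
    return float(1.0 - np.dot(profile.p, profile.p))


def _check_alignment(profile: AbundanceProfile, dist: FunctionalDistanceMatrix) -> None:
    if profile.taxa != dist.taxa:
        raise AlignmentError(
            "profile and distance matrix taxa differ: "
            f"{profile.taxa[:5]}... vs {dist.taxa[:5]}..."
        )


def functional_diversity(
    profile: AbundanceProfile, dist: FunctionalDistanceMatrix
) -> float:
    """Rao's quadratic entropy ``sum_{i != j} d_ij p_i p_j``."""
    _check_alignment(profile, dist)
    return float(profile.p @ dist.d @ profile.p)


def functional_redundancy(
    profile: AbundanceProfile, dist: FunctionalDistanceMatrix
) -> DiversitySummary:
    """Full diversity summary: TD, FD, FR = TD - FD and nFR = FR / TD.

    A single-taxon sample has TD = 0 and no pair to be redundant, so
    nFR is defined as 0 there.
    """
    _check_alignment(profile, dist)
    td = taxonomic_diversity(profile)
    fd = functional_diversity(profile, dist)
    fd = min(fd, td)  # guard rounding: FD <= TD holds analytically
    fr = td - fd
    nfr = fr / td if td > 0 else 0.0
    return DiversitySummary(td=td, fd=fd, fr=fr, nfr=nfr)


def sample_summary(
    net: TaxonFunctionNetwork, profile: AbundanceProfile
) -> DiversitySummary:
    """Per-sample composition: align taxa, compute d_ij in-sample, summarize.

    Taxa present in only one of the network and the profile are dropped
    and the proportions renormalized over the shared taxa.
    """
    shared = [t for t in net.taxa if t in set(profile.taxa)]
    if not shared:
        raise AlignmentError("network and profile share no taxa")
    index = {t: i for i, t in enumerate(net.taxa)}
    sub = TaxonFunctionNetwork(
        shared,
        list(net.functions),
        net.weights[[index[t] for t in shared]],
        net.kind,
    )
    dist = weighted_jaccard(sub)
    return functional_redundancy(profile.subset(shared), dist)
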