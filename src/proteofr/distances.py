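"""Cross-sample analysis of pairwise functional distances.

Collects per-sample weighted Jaccard distances d_ij between genus
proteomes into a long table, compares their distributions between groups
(disease vs control, drug vs vehicle) with Jensen-Shannon divergence and
per-pair rank-sum tests, and applies Benjamini-Hochberg correction over
genus pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceProfile, TaxonFunctionNetwork
from .diversity import weighted_jaccard
from .errors import ValidationError
from .network import filter_top_biomass

PAIR_COLUMNS = ["sample_id", "group_label", "taxon_i", "taxon_j", "d_ij"]


def _mean_profile(samples: list[tuple[TaxonFunctionNetwork, AbundanceProfile]]) -> AbundanceProfile:
    """Dataset-wide biomass: mean of per-sample proportions per genus."""
    totals: dict[str, float] = {}
    for _, profile in samples:
        for taxon, p in zip(profile.taxa, profile.p):
            totals[taxon] = totals.get(taxon, 0.0) + p
    taxa = sorted(totals)
    p = np.array([totals[t] for t in taxa])
    return AbundanceProfile(taxa, p / p.sum())


def collect_pairs(
    samples: list[tuple[TaxonFunctionNetwork, AbundanceProfile]],
    sample_ids: list[str] | None = None,
    group_labels: list[str] | None = None,
    biomass_fraction: float = 0.95,
) -> pd.DataFrame:
    """Per-sample d_ij values for genera in the dataset-wide top biomass.

    The retained genus set is chosen once from the mean biomass profile
    across all samples (the "top 95% of the dataset" rule); each sample
    then contributes one row per retained unordered genus pair present in
    that sample. Pairs with a genus absent from a sample are simply not
    emitted (absence of evidence, not maximal distance).
    """
    if not samples:
        raise ValidationError("collect_pairs needs at least one sample")
    n = len(samples)
    sample_ids = sample_ids or [f"S{k}" for k in range(n)]
    group_labels = group_labels or [""] * n
    if len(sample_ids) != n or len(group_labels) != n:
        raise ValidationError("sample_ids/group_labels length mismatch")

    retained = filter_top_biomass(_mean_profile(samples), biomass_fraction)
    rows = []
    for (net, _profile), sid, grp in zip(samples, sample_ids, group_labels):
        keep = [t for t in net.taxa if t in retained]
        if len(keep) < 2:
            continue
        index = {t: i for i, t in enumerate(net.taxa)}
        sub = TaxonFunctionNetwork(
            keep, list(net.functions), net.weights[[index[t] for t in keep]], net.kind
        )
        dist = weighted_jaccard(sub.row_normalized())
        order = sorted(range(len(keep)), key=lambda i: keep[i])
        for x, i in enumerate(order):
            for j in order[x + 1:]:
                rows.append((sid, grp, keep[i], keep[j], float(dist.d[i, j])))
    if not rows:
        raise ValidationError("no retained genus pair in any sample")
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def js_divergence(
    dist_a: np.ndarray, dist_b: np.ndarray, bins: int = 50, pseudocount: float = 1e-10
) -> float:
    """Jensen-Shannon divergence between two samples of d values.

    Both samples are histogrammed on the fixed grid [0, 1] with ``bins``
    equal-width bins, smoothed with a per-bin pseudo-count and
    normalized; the divergence uses log base 2, so the value lies in
    [0, 1] and is symmetric in its arguments.
    """
    dist_a = np.asarray(dist_a, dtype=float)
    dist_b = np.asarray(dist_b, dtype=float)
    if dist_a.size == 0 or dist_b.size == 0:
        raise ValidationError("js_divergence needs non-empty samples")
    edges = np.linspace(0.0, 1.0, bins + 1)
    pa = np.histogram(dist_a, bins=edges)[0].astype(float) + pseudocount
    pb = np.histogram(dist_b, bins=edges)[0].astype(float) + pseudocount
    pa /= pa.sum()
    pb /= pb.sum()
    m = 0.5 * (pa + pb)
    kl_am = np.sum(pa * np.log2(pa / m))
    kl_bm = np.sum(pb * np.log2(pb / m))
    return float(0.5 * kl_am + 0.5 * kl_bm)


def group_js_divergence(
    table: pd.DataFrame, group_a: str, group_b: str, bins: int = 50,
    shared_pairs_only: bool = True,
) -> float:
    """JSD between the pooled d_ij distributions of two groups.

    By default only genus pairs observed in both groups are pooled, so
    the comparison reflects shifted distances rather than differing pair
    composition.
    """
    a = table[table["group_label"] == group_a]
    b = table[table["group_label"] == group_b]
    if a.empty or b.empty:
        raise ValidationError("both groups must have samples")
    if shared_pairs_only:
        key = ["taxon_i", "taxon_j"]
        shared = pd.merge(a[key].drop_duplicates(), b[key].drop_duplicates(), on=key)
        a = pd.merge(a, shared, on=key)
        b = pd.merge(b, shared, on=key)
        if a.empty or b.empty:
            raise ValidationError("groups share no genus pair")
    return js_divergence(a["d_ij"].to_numpy(), b["d_ij"].to_numpy(), bins=bins)


def pairwise_group_comparison(
    table: pd.DataFrame, group_a: str, group_b: str, min_samples: int = 2
) -> pd.DataFrame:
    """Per-genus-pair comparison of d_ij between two groups.

    For each pair observed in at least ``min_samples`` samples of each
    group: log2 fold change of mean d_ij (b over a), a two-sided
    Wilcoxon rank-sum p-value, and Benjamini-Hochberg adjusted p across
    pairs.
    """
    a = table[table["group_label"] == group_a]
    b = table[table["group_label"] == group_b]
    if a.empty or b.empty:
        raise ValidationError("both groups must have samples")
    rows = []
    grouped_a = a.groupby(["taxon_i", "taxon_j"])["d_ij"]
    grouped_b = b.groupby(["taxon_i", "taxon_j"])["d_ij"]
    means_b = {k: g for k, g in grouped_b}
    for key, va in grouped_a:
        vb = means_b.get(key)
        if vb is None or len(va) < min_samples or len(vb) < min_samples:
            continue
        mean_a, mean_b_ = va.mean(), vb.mean()
        if mean_a <= 0 or mean_b_ <= 0:
            log2fc = np.nan
        else:
            log2fc = float(np.log2(mean_b_ / mean_a))
        if np.ptp(np.concatenate([va.to_numpy(), vb.to_numpy()])) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(vb, va, alternative="two-sided").pvalue)
        rows.append(
            {"taxon_i": key[0], "taxon_j": key[1], "log2fc": log2fc, "p": p}
        )
    if not rows:
        raise ValidationError("no genus pair meets the per-group sample minimum")
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
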