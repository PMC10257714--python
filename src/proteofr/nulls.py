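"""GCN-constrained randomizations of a proteomic content network.

A sample's PCN is a sub-network of its GCN (a function must be encoded
before it can be expressed), so meaningful null networks are drawn from
the GCN's edge set only. Four variants differ in what they preserve of
the natural PCN:

* null1 — completely random: the PCN's edge count, edges uniform over
  GCN edges;
* null2 — preserves every taxon's degree (per-taxon uniform subsets of
  its GCN functions);
* null3 — preserves every function's degree (per-function uniform
  subsets of its GCN taxa);
* null4 — preserves both degree sequences, via checkerboard trade moves
  restricted to GCN-admissible cells.

After randomization each taxon's new edges are weighted either uniformly
(1/degree, the default) or by permuting the taxon's original weight
multiset over its new edges (only defined when taxon degrees are
preserved, i.e. null2/null4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AbundanceProfile, TaxonFunctionNetwork
from .diversity import sample_summary
from .errors import InfeasibleError, ValidationError
from .topology import nodf

logger = logging.getLogger(__name__)

_VARIANT_FLAGS = {
    "null1": (False, False),
    "null2": (True, False),
    "null3": (False, True),
    "null4": (True, True),
}


@dataclass(frozen=True)
class NullSpec:
    """Which null variant to draw, how many replicates, and the seed."""

    variant: str
    n_replicates: int = 10
    seed: int = 0
    weight_policy: str = "uniform"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_FLAGS:
            raise ValidationError(f"unknown null variant {self.variant!r}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be positive")
        if self.weight_policy not in ("uniform", "permute"):
            raise ValidationError(f"unknown weight policy {self.weight_policy!r}")
        if self.weight_policy == "permute" and not self.preserve_taxon_degree:
            raise ValidationError(
                "weight policy 'permute' needs preserved taxon degrees (null2/null4)"
            )

    @property
    def preserve_taxon_degree(self) -> bool:
        return _VARIANT_FLAGS[self.variant][0]

    @property
    def preserve_function_degree(self) -> bool:
        return _VARIANT_FLAGS[self.variant][1]


def restrict_to_background(
    pcn: TaxonFunctionNetwork, gcn: TaxonFunctionNetwork
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], int]:
    """Map PCN and GCN onto the GCN's label space; drop off-background edges.

    Returns (pcn_binary, gcn_binary, taxa, functions, n_dropped) where the
    binary matrices are indexed by the GCN's taxa and functions. PCN taxa
    or functions missing from the GCN, and PCN edges not present in the
    GCN (possible in real data through annotation mismatches), are dropped
    with a logged count so the background constraint holds exactly.
    """
    taxa = list(gcn.taxa)
    functions = list(gcn.functions)
    ti = {t: i for i, t in enumerate(taxa)}
    fi = {f: i for i, f in enumerate(functions)}
    g = gcn.binary()
    p = np.zeros_like(g)
    dropped = 0
    rows, cols = np.nonzero(pcn.weights)
    for i, a in zip(rows, cols):
        t, f = pcn.taxa[i], pcn.functions[a]
        if t in ti and f in fi and g[ti[t], fi[f]]:
            p[ti[t], fi[f]] = True
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d PCN edges not present in the GCN background", dropped)
    if not p.any():
        raise InfeasibleError("no PCN edge lies on the GCN background")
    return p, g, taxa, functions, dropped


def _check_feasible(p: np.ndarray, g: np.ndarray, taxa: list[str], functions: list[str]) -> None:
    row_bad = np.nonzero(p.sum(axis=1) > g.sum(axis=1))[0]
    if row_bad.size:
        raise InfeasibleError(
            f"taxon {taxa[row_bad[0]]!r}: PCN degree exceeds GCN degree"
        )
    col_bad = np.nonzero(p.sum(axis=0) > g.sum(axis=0))[0]
    if col_bad.size:
        raise InfeasibleError(
            f"function {functions[col_bad[0]]!r}: PCN degree exceeds GCN degree"
        )


def _draw_binary(
    p: np.ndarray, g: np.ndarray, spec: NullSpec, rng: np.random.Generator, state: dict
) -> np.ndarray:
    """Draw one binary replicate according to the variant's constraints."""
    if spec.variant == "null1":
        gi, ga = np.nonzero(g)
        k = int(p.sum())
        pick = rng.choice(gi.size, size=k, replace=False)
        out = np.zeros_like(p)
        out[gi[pick], ga[pick]] = True
        return out
    if spec.variant == "null2":
        out = np.zeros_like(p)
        for i in range(p.shape[0]):
            k = int(p[i].sum())
            if k == 0:
                continue
            support = np.nonzero(g[i])[0]
            out[i, rng.choice(support, size=k, replace=False)] = True
        return out
    if spec.variant == "null3":
        out = np.zeros_like(p)
        for a in range(p.shape[1]):
            k = int(p[:, a].sum())
            if k == 0:
                continue
            support = np.nonzero(g[:, a])[0]
            out[rng.choice(support, size=k, replace=False), a] = True
        return out
    # null4: checkerboard trades restricted to GCN-admissible cells,
    # run as a single chain; 5 x (edge count) successful trades between
    # returned samples (and as burn-in before the first).
    current = state.setdefault("chain", p.copy())
    n_trades = 5 * int(p.sum())
    edges_i, edges_a = np.nonzero(current)
    n_edges = edges_i.size
    if n_edges < 2:
        return current.copy()
    done = 0
    attempts = 0
    max_attempts = 2000 * n_trades  # bail out on frozen configurations
    while done < n_trades and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, n_edges, size=2)
        i, a = edges_i[e1], edges_a[e1]
        j, b = edges_i[e2], edges_a[e2]
        if i == j or a == b:
            continue
        if current[i, b] or current[j, a]:
            continue
        if not (g[i, b] and g[j, a]):
            continue
        current[i, a] = current[j, b] = False
        current[i, b] = current[j, a] = True
        edges_a[e1], edges_a[e2] = b, a
        done += 1
    return current.copy()


def _apply_weights(
    binary: np.ndarray,
    pcn_weights: np.ndarray,
    policy: str,
    rng: np.random.Generator,
) -> np.ndarray:
    w = np.zeros(binary.shape)
    for i in range(binary.shape[0]):
        support = np.nonzero(binary[i])[0]
        if support.size == 0:
            continue
        if policy == "uniform":
            w[i, support] = 1.0 / support.size
        else:  # permute original row weights over the new edges
            original = pcn_weights[i][pcn_weights[i] > 0]
            if original.size != support.size:
                raise InfeasibleError(
                    "permute weight policy requires preserved taxon degrees"
                )
            w[i, support] = rng.permutation(original)
    return w


def randomize(
    pcn: TaxonFunctionNetwork, gcn: TaxonFunctionNetwork, spec: NullSpec
) -> list[TaxonFunctionNetwork]:
    """Draw ``spec.n_replicates`` null PCNs under the GCN background.

    Every replicate's edges are a subset of the GCN's edges; edge count
    equals the (background-restricted) PCN's edge count; degree sequences
    are preserved exactly as declared by the variant.
    """
    p, g, taxa, functions, _ = restrict_to_background(pcn, gcn)
    _check_feasible(p, g, taxa, functions)

    # original PCN weights in the GCN label space, for the permute policy
    ti = {t: i for i, t in enumerate(taxa)}
    fi = {f: i for i, f in enumerate(functions)}
    pw = np.zeros(p.shape)
    for i, a in zip(*np.nonzero(pcn.weights)):
        t, f = pcn.taxa[i], pcn.functions[a]
        if t in ti and f in fi and p[ti[t], fi[f]]:
            pw[ti[t], fi[f]] = pcn.weights[i, a]

    rng = np.random.default_rng(spec.seed)
    state: dict = {}
    replicates = []
    for _ in range(spec.n_replicates):
        binary = _draw_binary(p, g, spec, rng, state)
        weights = _apply_weights(binary, pw, spec.weight_policy, rng)
        replicates.append(TaxonFunctionNetwork(list(taxa), list(functions), weights, "pcn"))
    return replicates


def _drop_zero_rows(net: TaxonFunctionNetwork) -> TaxonFunctionNetwork:
    keep = net.weights.sum(axis=1) > 0
    return TaxonFunctionNetwork(
        [t for t, k in zip(net.taxa, keep) if k],
        list(net.functions),
        net.weights[keep],
        net.kind,
    )


def null_fr_comparison(
    pcn: TaxonFunctionNetwork,
    gcn: TaxonFunctionNetwork,
    profile: AbundanceProfile,
    variants: list[str] | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    weight_policy: str = "uniform",
) -> pd.DataFrame:
    """Diversity and nestedness of the natural PCN and its null replicates.

    Returns one row per (variant, replicate) with td, fd, fr, nfr and
    nodf, plus a 'natural' row computed from the input PCN itself.
    """
    variants = variants or ["null1", "null2", "null3", "null4"]
    rows = []

    def metrics(net: TaxonFunctionNetwork) -> dict[str, float]:
        active = _drop_zero_rows(net)
        normalized = active.row_normalized()
        summary = sample_summary(normalized, profile)
        return {**summary.to_dict(), "nodf": nodf(active).nodf}

    rows.append({"variant": "natural", "replicate": 0, **metrics(pcn)})
    for variant in variants:
        spec = NullSpec(
            variant=variant,
            n_replicates=n_replicates,
            seed=seed,
            weight_policy=weight_policy,
        )
        for r, rep in enumerate(randomize(pcn, gcn, spec)):
            rows.append({"variant": variant, "replicate": r, **metrics(rep)})
    return pd.DataFrame(rows)
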