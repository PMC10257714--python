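"""Core domain types for taxon-function content networks.

A microbiome sample is represented by three layers:

* per-peptide and per-protein-group evidence (``PeptideRecord``,
  ``ProteinGroupRecord``) or per-gene read counts (``GeneRecord``);
* a weighted bipartite taxon-function network (``TaxonFunctionNetwork``),
  either a proteomic content network (PCN, weighted by protein intensity)
  or a genomic content network (GCN, weighted by read counts);
* per-taxon biomass proportions (``AbundanceProfile``) and the derived
  functional distance matrix and diversity summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ValidationError

#: Taxonomic ranks in fixed order, used when parsing LCA lineages.
RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

ROW_SUM_TOL = 1e-9


def parse_lineage(text: str) -> tuple[tuple[str, str], ...]:
    """Parse a ``rank:name;rank:name`` lineage string.

    Ranks must appear in :data:`RANKS` order; empty string means an empty
    lineage (peptide not taxonomically resolved).
    """
    text = text.strip()
    if not text:
        return ()
    out: list[tuple[str, str]] = []
    last = -1
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        rank, _, name = part.partition(":")
        if rank not in _RANK_INDEX:
            raise ValidationError(f"unknown taxonomic rank {rank!r} in lineage {text!r}")
        idx = _RANK_INDEX[rank]
        if idx <= last:
            raise ValidationError(f"lineage ranks out of order in {text!r}")
        last = idx
        out.append((rank, name))
    return tuple(out)


def format_lineage(lineage: tuple[tuple[str, str], ...]) -> str:
    return ";".join(f"{rank}:{name}" for rank, name in lineage)


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with its MS intensity and LCA lineage."""

    peptide_id: str
    sequence: str
    intensity: float
    is_unique: bool
    lca_lineage: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: negative intensity {self.intensity}"
            )
        if self.is_unique and not self.lca_lineage:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: unique peptide without a lineage"
            )

    @property
    def genus(self) -> str | None:
        """Genus name if the LCA is at or below genus level, else ``None``."""
        for rank, name in self.lca_lineage:
            if rank == "genus" and name:
                return name
        return None


@dataclass(frozen=True)
class ProteinGroupRecord:
    """A quantified protein group and its member peptides."""

    group_id: str
    peptide_ids: frozenset[str]
    intensity: float
    ko: str | None = None
    cog: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide_ids:
            raise ValidationError(f"protein group {self.group_id!r}: no peptide ids")
        if self.intensity < 0:
            raise ValidationError(
                f"protein group {self.group_id!r}: negative intensity {self.intensity}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """One predicted gene with taxon, function and read count."""

    gene_id: str
    taxon: str
    function_id: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValidationError(
                f"gene {self.gene_id!r}: negative read count {self.read_count}"
            )


@dataclass
class TaxonFunctionNetwork:
    """Weighted bipartite incidence matrix of taxa (rows) by functions.

    ``weights[i, a]`` is the normalized quantification of function ``a``
    in taxon ``i`` (protein intensity for a PCN, read counts for a GCN).
    After construction every retained row is normalized to sum to 1.
    """

    taxa: list[str]
    functions: list[str]
    weights: np.ndarray
    kind: str = "pcn"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.taxa), len(self.functions)):
            raise ValidationError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.functions)} functions"
            )
        if self.kind not in ("pcn", "gcn"):
            raise ValidationError(f"network kind must be 'pcn' or 'gcn', got {self.kind!r}")
        if np.any(self.weights < 0):
            raise ValidationError("network weights must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_functions(self) -> int:
        return len(self.functions)

    def binary(self) -> np.ndarray:
        """Presence/absence incidence (weight strictly positive)."""
        return self.weights > 0

    def edge_set(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.weights)
        return {(self.taxa[i], self.functions[a]) for i, a in zip(rows, cols)}

    def row_normalized(self) -> "TaxonFunctionNetwork":
        """Return a copy with every nonzero row scaled to sum to 1."""
        w = self.weights.copy()
        sums = w.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        w[nz] /= sums[nz]
        return TaxonFunctionNetwork(list(self.taxa), list(self.functions), w, self.kind)

    def is_row_stochastic(self, tol: float = ROW_SUM_TOL) -> bool:
        sums = self.weights.sum(axis=1)
        nz = sums > 0
        return bool(np.all(np.abs(sums[nz] - 1.0) <= tol))


@dataclass
class AbundanceProfile:
    """Per-taxon biomass proportions ``p_i`` within one sample."""

    taxa: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.taxa),):
            raise ValidationError("proportion vector length does not match taxa")
        if np.any(self.p < 0):
            raise ValidationError("proportions must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"proportions sum to {self.p.sum()}, expected 1")

    def subset(self, taxa: list[str]) -> "AbundanceProfile":
        """Restrict to ``taxa`` (in the given order) and renormalize."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise AlignmentError(f"taxa not in profile: {missing}")
        p = self.p[[index[t] for t in taxa]]
        total = p.sum()
        if total <= 0:
            raise ValidationError("subset has zero total biomass")
        return AbundanceProfile(list(taxa), p / total)


@dataclass
class FunctionalDistanceMatrix:
    """Symmetric matrix of pairwise weighted Jaccard distances in [0, 1]."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        s = len(self.taxa)
        if self.d.shape != (s, s):
            raise ValidationError("distance matrix shape does not match taxa")
        if np.any(self.d < -1e-12) or np.any(self.d > 1 + 1e-12):
            raise ValidationError("distances must lie in [0, 1]")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("self-distances must be zero")


@dataclass(frozen=True)
class DiversitySummary:
    """Taxonomic diversity, functional diversity, and redundancy of a sample.

    ``td`` is the Gini-Simpson index, ``fd`` Rao's quadratic entropy,
    ``fr = td - fd`` the functional redundancy, and ``nfr = fr / td`` its
    normalized form (0 when ``td`` is 0).
    """

    td: float
    fd: float
    fr: float
    nfr: float

    def __post_init__(self) -> None:
        if abs(self.fr - (self.td - self.fd)) > 1e-12:
            raise ValidationError("fr must equal td - fd")
        if self.fd < -1e-12 or self.fd > self.td + 1e-12:
            raise ValidationError("fd must lie in [0, td]")

    def to_dict(self) -> dict[str, float]:
        return {"td": self.td, "fd": self.fd, "fr": self.fr, "nfr": self.nfr}
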