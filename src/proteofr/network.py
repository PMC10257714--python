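"""Construction of content networks and biomass profiles.

The proteomic content network (PCN) links genera to the functions their
expressed proteins are annotated with. Because protein groups carry the
functional annotation while taxonomy is resolved per peptide, the two are
joined by a peptide-protein bridge: each protein group's intensity is
distributed over the genera supported by its genus-resolved unique
peptides, proportionally to the summed unique-peptide intensity per genus.
The genomic content network (GCN) is built directly from per-gene read
counts. Both matrices are row-normalized so each taxon's weights describe
its within-taxon functional profile.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    AbundanceProfile,
    GeneRecord,
    PeptideRecord,
    ProteinGroupRecord,
    TaxonFunctionNetwork,
)
from .errors import EmptyNetworkError, ValidationError


@dataclass(frozen=True)
class BridgeAssignment:
    """Share of one protein group's intensity attributed to one genus."""

    group_id: str
    genus: str
    assigned_intensity: float


def merge_annotations(groups: list[ProteinGroupRecord]) -> dict[str, str]:
    """Merge KO and COG annotations into a single function id per group.

    KEGG KO takes precedence; COG fills in for groups without a KO.
    Groups with neither annotation are excluded (and thus absent from the
    PCN). KO and COG id namespaces do not collide (K##### vs COG####).
    """
    merged: dict[str, str] = {}
    for g in groups:
        fn = g.ko or g.cog
        if fn:
            merged[g.group_id] = fn
    return merged


def bridge_proteins_to_taxa(
    groups: list[ProteinGroupRecord], peptides: list[PeptideRecord]
) -> list[BridgeAssignment]:
    """Distribute protein-group intensities over genera via unique peptides.

    For each group, only member peptides that are unique and resolved to
    genus level (or below) count; the group's intensity is split across
    those genera proportionally to per-genus summed unique-peptide
    intensity. Groups with no genus-resolved unique peptide yield no
    assignment. The split conserves the group's total intensity.
    """
    by_id = {p.peptide_id: p for p in peptides}
    assignments: list[BridgeAssignment] = []
    for g in groups:
        missing = sorted(pid for pid in g.peptide_ids if pid not in by_id)
        if missing:
            raise ValidationError(
                f"protein group {g.group_id!r} references unknown peptides: {missing}"
            )
        genus_intensity: dict[str, float] = defaultdict(float)
        for pid in g.peptide_ids:
            pep = by_id[pid]
            if pep.is_unique and pep.genus is not None:
                genus_intensity[pep.genus] += pep.intensity
        total = sum(genus_intensity.values())
        if total <= 0:
            continue
        for genus in sorted(genus_intensity):
            assignments.append(
                BridgeAssignment(g.group_id, genus, g.intensity * genus_intensity[genus] / total)
            )
    return assignments


def _assemble(
    cells: dict[tuple[str, str], float], kind: str
) -> TaxonFunctionNetwork:
    """Turn (taxon, function) -> weight cells into a row-normalized network."""
    taxa = sorted({t for t, _ in cells})
    functions = sorted({f for _, f in cells})
    if not taxa:
        raise EmptyNetworkError("no taxon received any weight")
    ti = {t: i for i, t in enumerate(taxa)}
    fi = {f: i for i, f in enumerate(functions)}
    weights = np.zeros((len(taxa), len(functions)))
    for (t, f), w in cells.items():
        weights[ti[t], fi[f]] += w
    keep = weights.sum(axis=1) > 0
    if not keep.any():
        raise EmptyNetworkError("all taxon rows are zero")
    taxa = [t for t, k in zip(taxa, keep) if k]
    weights = weights[keep]
    weights /= weights.sum(axis=1, keepdims=True)
    return TaxonFunctionNetwork(taxa, functions, weights, kind)


def build_pcn(
    groups: list[ProteinGroupRecord], peptides: list[PeptideRecord]
) -> TaxonFunctionNetwork:
    """Build the proteomic content network for one sample.

    Cell (i, a) accumulates the bridged intensities of all KEGG-COG
    annotated groups with function a in genus i; rows are then normalized
    by the taxon's total, so each row is that genus's expressed functional
    profile. Unannotated groups are dropped before normalization.
    """
    functions = merge_annotations(groups)
    annotated = [g for g in groups if g.group_id in functions]
    if not annotated:
        raise EmptyNetworkError("no protein group carries a KO or COG annotation")
    assignments = bridge_proteins_to_taxa(annotated, peptides)
    cells: dict[tuple[str, str], float] = defaultdict(float)
    for a in assignments:
        cells[(a.genus, functions[a.group_id])] += a.assigned_intensity
    if not cells:
        raise EmptyNetworkError("no protein group could be bridged to a genus")
    return _assemble(cells, "pcn")


def build_gcn(genes: list[GeneRecord]) -> TaxonFunctionNetwork:
    """Build the genomic content network from per-gene read counts."""
    cells: dict[tuple[str, str], float] = defaultdict(float)
    for g in genes:
        cells[(g.taxon, g.function_id)] += float(g.read_count)
    cells = {k: v for k, v in cells.items() if v > 0}
    if not cells:
        raise EmptyNetworkError("no gene has a positive read count")
    return _assemble(cells, "gcn")


def biomass_profile(peptides: list[PeptideRecord]) -> AbundanceProfile:
    """Per-genus biomass proportions from unique-peptide intensity sums.

    Only unique peptides whose LCA is at or below genus level contribute;
    each genus's biomass is the sum of its unique-peptide intensities,
    normalized over all genera.
    """
    totals: dict[str, float] = defaultdict(float)
    for pep in peptides:
        if pep.is_unique and pep.genus is not None:
            totals[pep.genus] += pep.intensity
    totals = {g: v for g, v in totals.items() if v > 0}
    if not totals:
        raise ValidationError("no genus-resolved unique peptide with positive intensity")
    taxa = sorted(totals)
    p = np.array([totals[t] for t in taxa])
    return AbundanceProfile(taxa, p / p.sum())


def filter_top_biomass(profile: AbundanceProfile, fraction: float = 0.95) -> set[str]:
    """Genera making up the top ``fraction`` of biomass.

    Genera are ranked by descending proportion; the smallest prefix whose
    cumulative proportion first reaches ``fraction`` is returned (the
    genus crossing the threshold is included). Genera tied in abundance
    with the boundary genus are all included, for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    order = np.argsort(-profile.p, kind="stable")
    selected: set[str] = set()
    cum = 0.0
    boundary = None
    for idx in order:
        if boundary is not None and profile.p[idx] < boundary:
            break
        selected.add(profile.taxa[idx])
        cum += profile.p[idx]
        if boundary is None and cum >= fraction - 1e-12:
            boundary = profile.p[idx]
    return selected
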