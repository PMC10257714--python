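"""Tab-separated readers and writers for the package's table schemas.

All tables are UTF-8 TSV with a header row. Schemas are deliberately
minimal: they carry exactly the fields the taxon-function bridge uses
(peptide intensities and LCA lineages, protein-group intensities with
KO/COG annotations, gene read counts). Intensities are assumed to be
already sample-normalized; no cross-sample normalization happens here.

Parsing is strict: a missing column raises :class:`~proteofr.errors.SchemaError`
naming the column, and a malformed value raises
:class:`~proteofr.errors.ValidationError` naming the (1-based) data row.
Rows are never silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceProfile,
    DiversitySummary,
    GeneRecord,
    PeptideRecord,
    ProteinGroupRecord,
    TaxonFunctionNetwork,
    format_lineage,
    parse_lineage,
)
from .errors import SchemaError, ValidationError

_PEPTIDE_COLS = ["peptide_id", "sequence", "intensity", "is_unique", "lineage"]
_PROTEIN_COLS = ["group_id", "peptide_ids", "intensity", "ko", "cog"]
_GENE_COLS = ["gene_id", "taxon", "function_id", "read_count"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _parse_float(value: str, what: str, row: int) -> float:
    try:
        x = float(value)
    except ValueError:
        raise ValidationError(f"row {row}: {what} {value!r} is not a number") from None
    if not np.isfinite(x):
        raise ValidationError(f"row {row}: {what} {value!r} is not finite")
    if x < 0:
        raise ValidationError(f"row {row}: {what} {value!r} is negative")
    return x


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide table (MetaLab-style taxonomy/peptide output schema)."""
    df = _read_tsv(path, _PEPTIDE_COLS)
    records = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        flag = rec.is_unique.strip().lower()
        if flag in _TRUE:
            unique = True
        elif flag in _FALSE:
            unique = False
        else:
            raise ValidationError(f"row {row}: is_unique {rec.is_unique!r} is not boolean")
        try:
            records.append(
                PeptideRecord(
                    peptide_id=rec.peptide_id,
                    sequence=rec.sequence,
                    intensity=_parse_float(rec.intensity, "intensity", row),
                    is_unique=unique,
                    lca_lineage=parse_lineage(rec.lineage),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {row}: {err}") from None
    return records


def write_peptide_table(records: list[PeptideRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in records],
            "sequence": [r.sequence for r in records],
            "intensity": [repr(r.intensity) for r in records],
            "is_unique": ["true" if r.is_unique else "false" for r in records],
            "lineage": [format_lineage(r.lca_lineage) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_protein_table(path: str | Path) -> list[ProteinGroupRecord]:
    """Read a protein-groups table (MaxQuant-style output schema)."""
    df = _read_tsv(path, _PROTEIN_COLS)
    records = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        peptide_ids = frozenset(p for p in rec.peptide_ids.split(";") if p.strip())
        if not peptide_ids:
            raise ValidationError(f"row {row}: protein group {rec.group_id!r} has no peptide ids")
        records.append(
            ProteinGroupRecord(
                group_id=rec.group_id,
                peptide_ids=peptide_ids,
                intensity=_parse_float(rec.intensity, "intensity", row),
                ko=rec.ko.strip() or None,
                cog=rec.cog.strip() or None,
            )
        )
    return records


def write_protein_table(records: list[ProteinGroupRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "group_id": [r.group_id for r in records],
            "peptide_ids": [";".join(sorted(r.peptide_ids)) for r in records],
            "intensity": [repr(r.intensity) for r in records],
            "ko": [r.ko or "" for r in records],
            "cog": [r.cog or "" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene table: taxon, function and raw read count per gene."""
    df = _read_tsv(path, _GENE_COLS)
    records = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            count = int(rec.read_count)
        except ValueError:
            raise ValidationError(
                f"row {row}: read_count {rec.read_count!r} is not an integer"
            ) from None
        if count < 0:
            raise ValidationError(f"row {row}: read_count {count} is negative")
        records.append(
            GeneRecord(
                gene_id=rec.gene_id,
                taxon=rec.taxon,
                function_id=rec.function_id,
                read_count=count,
            )
        )
    return records


def write_gene_table(records: list[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "taxon": [r.taxon for r in records],
            "function_id": [r.function_id for r in records],
            "read_count": [r.read_count for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_network(net: TaxonFunctionNetwork, path: str | Path) -> None:
    """Write the nonzero entries of a network as long-format TSV.

    Rows are ordered lexicographically by taxon then function so output
    is deterministic regardless of in-memory ordering.
    """
    rows = []
    for i, taxon in enumerate(net.taxa):
        for a, function in enumerate(net.functions):
            w = net.weights[i, a]
            if w > 0:
                rows.append((taxon, function, repr(float(w))))
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=["taxon", "function", "weight"])
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, kind: str = "pcn") -> TaxonFunctionNetwork:
    """Read a long-format network TSV back into an incidence matrix.

    Taxa and functions are ordered lexicographically (the same order
    :func:`write_network` emits), so write-then-read is an exact inverse
    up to that canonical ordering.
    """
    df = _read_tsv(path, ["taxon", "function", "weight"])
    taxa = sorted(df["taxon"].unique())
    functions = sorted(df["function"].unique())
    ti = {t: i for i, t in enumerate(taxa)}
    fi = {f: i for i, f in enumerate(functions)}
    weights = np.zeros((len(taxa), len(functions)))
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        weights[ti[rec.taxon], fi[rec.function]] = _parse_float(rec.weight, "weight", row)
    return TaxonFunctionNetwork(taxa, functions, weights, kind)


def write_profile(profile: AbundanceProfile, path: str | Path) -> None:
    """Write a two-column biomass TSV (genus, proportion)."""
    df = pd.DataFrame(
        {"taxon": profile.taxa, "proportion": [repr(float(x)) for x in profile.p]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path) -> AbundanceProfile:
    df = _read_tsv(path, ["taxon", "proportion"])
    p = np.array(
        [_parse_float(v, "proportion", i) for i, v in enumerate(df["proportion"], start=1)]
    )
    return AbundanceProfile(list(df["taxon"]), p)


def write_summary(summary: DiversitySummary, path: str | Path, **extra) -> None:
    """Export a diversity summary (plus optional metadata) as JSON."""
    payload = dict(extra)
    payload.update(summary.to_dict())
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
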