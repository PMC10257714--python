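"""Synthetic metaproteomic/metagenomic datasets with controllable structure.

Real content networks are nested with fat-tailed degree distributions:
a few generalist genera express most functions while many specialists
express a small subset of them. The generator reproduces this by
building a perfectly nested (prefix-support) PCN incidence matrix from a
geometrically decaying row-degree sequence and then degrading it with
degree-preserving checkerboard swaps until the realized NODF falls to
the requested target. The paired GCN is a random edge-superset of the
PCN, so the expressed network is always a sub-network of the encoded one.

From the base networks the generator emits per-sample peptide, protein
and gene tables in the package's TSV schemas: one annotated protein
group per PCN edge, bridged to its genus by a unique peptide whose
intensity also encodes the genus biomass, plus a sprinkling of
non-unique and above-genus peptides to exercise the exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    AbundanceProfile,
    GeneRecord,
    PeptideRecord,
    ProteinGroupRecord,
    TaxonFunctionNetwork,
)
from .errors import InfeasibleError, ValidationError
from .topology import nodf


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generator.

    ``nestedness_target`` is the NODF the built per-sample PCN should
    realize (within 0.1); ``pcn_connectance`` its fill;
    ``pcn_fraction_of_gcn`` the ratio of PCN to GCN edge counts (the
    expressed fraction of the encoded repertoire); ``group_effect``, if
    set, multiplies a block of functions by 2**shift in samples of the
    second half ("case" group).
    """

    n_taxa: int = 30
    n_functions: int = 120
    nestedness_target: float = 0.35
    pcn_connectance: float = 0.12
    weight_distribution: str = "lognormal"
    pcn_fraction_of_gcn: float = 0.25
    n_samples: int = 4
    group_effect: float | None = None
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_taxa, self.n_functions, self.n_samples) < 1:
            raise ValidationError("counts must be positive")
        if not 0 <= self.nestedness_target <= 1:
            raise ValidationError("nestedness_target must be in [0, 1]")
        if not 0 < self.pcn_fraction_of_gcn <= 1:
            raise ValidationError("pcn_fraction_of_gcn must be in (0, 1]")
        if not 0 < self.pcn_connectance <= 1:
            raise ValidationError("pcn_connectance must be in (0, 1]")
        if self.weight_distribution not in ("lognormal", "uniform"):
            raise ValidationError(
                f"weight_distribution must be lognormal or uniform, got {self.weight_distribution!r}"
            )


@dataclass
class SampleTables:
    """The three input tables of one synthetic sample."""

    sample_id: str
    group_label: str
    peptides: list[PeptideRecord]
    proteins: list[ProteinGroupRecord]
    genes: list[GeneRecord]


@dataclass
class SyntheticDataset:
    samples: list[SampleTables]
    pcn_support: np.ndarray
    gcn_support: np.ndarray
    taxa: list[str]
    functions: list[str]
    realized_nodf: float
    manifest: dict = field(default_factory=dict)


def _nested_support(S: int, F: int, connectance: float) -> np.ndarray:
    """Prefix-support incidence with geometrically decaying row degrees."""
    n_edges = max(S, round(connectance * S * F))
    if n_edges > S * F:
        raise InfeasibleError("connectance implies more edges than cells")
    # geometric decay gives the fat-tailed degree sequence; scale to the
    # edge budget, clip to [1, F], then greedily fix the total
    decay = 0.85
    raw = decay ** np.arange(S)
    k = np.maximum(1, np.round(raw * n_edges / raw.sum()).astype(int))
    k = np.minimum(k, F)
    k[::-1].sort()
    diff = n_edges - k.sum()
    i = 0
    while diff != 0:
        step = 1 if diff > 0 else -1
        if 1 <= k[i % S] + step <= F:
            k[i % S] += step
            diff -= step
        i += 1
        if i > 100 * S:
            break
    k[::-1].sort()
    b = np.zeros((S, F), dtype=bool)
    for i in range(S):
        b[i, : k[i]] = True
    return b


def _measure_nodf(mat: np.ndarray) -> float:
    # network construction drops functions with no incidence, so the
    # realized NODF is that of the nonempty submatrix
    sub = mat[mat.any(axis=1)][:, mat.any(axis=0)]
    return nodf(TaxonFunctionNetwork(
        [f"t{i}" for i in range(sub.shape[0])],
        [f"f{a}" for a in range(sub.shape[1])],
        sub.astype(float),
    )).nodf


def _rewire(b: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Move ``m`` edges of ``b`` to uniformly random empty cells.

    Rows are never emptied (each keeps at least one edge), so every taxon
    survives network construction. ``m = 0`` returns the nested support
    unchanged; ``m`` near the edge count gives an essentially random
    support with the same fill.
    """
    out = b.copy()
    edges = np.flatnonzero(out.ravel())
    removable = rng.permutation(edges)
    removed = 0
    for e in removable:
        if removed >= m:
            break
        i = e // out.shape[1]
        if out[i].sum() <= 1:
            continue
        out.ravel()[e] = False
        removed += 1
    empty = np.flatnonzero(~out.ravel())
    pick = rng.choice(empty.size, size=removed, replace=False)
    out.ravel()[empty[pick]] = True
    return out


def _calibrate_support(
    b: np.ndarray, target: float, seed: int, tol: float = 0.1
) -> tuple[np.ndarray, float]:
    """Find a support whose realized NODF is within ``tol`` of target.

    Bisects the number of rewired edges between 0 (the nested staircase,
    maximal NODF) and the full edge count (a random support with the
    same fill, minimal NODF). NODF is only statistically monotone in the
    rewiring depth, so the search keeps the best candidate seen.
    """
    n_edges = int(b.sum())
    top = _measure_nodf(b)
    if target > top + tol:
        raise InfeasibleError(
            f"nestedness target {target} above the achievable maximum {top:.3f}"
        )
    if target >= top:
        return b.copy(), top

    def candidate(m: int, attempt: int) -> tuple[np.ndarray, float]:
        rng = np.random.default_rng((seed, m, attempt))
        mat = _rewire(b, m, rng)
        return mat, _measure_nodf(mat)

    best_mat, best_val = b.copy(), top
    lo, hi = 0, n_edges
    floor_mat, floor_val = candidate(n_edges, 0)
    if target < floor_val - tol:
        raise InfeasibleError(
            f"nestedness target {target} below the reachable minimum {floor_val:.3f} "
            "for these dimensions and connectance"
        )
    if abs(floor_val - target) < abs(best_val - target):
        best_mat, best_val = floor_mat, floor_val
    for attempt in range(40):
        if abs(best_val - target) <= tol / 2:
            break
        mid = (lo + hi) // 2
        mat, val = candidate(mid, attempt)
        if abs(val - target) < abs(best_val - target):
            best_mat, best_val = mat, val
        if val > target:
            lo = mid + 1
        else:
            hi = mid - 1
        if lo > hi:
            lo, hi = 0, n_edges  # restart with a fresh realization
    if abs(best_val - target) > tol:
        raise InfeasibleError(
            f"could not reach nestedness {target}: best realized {best_val:.3f}"
        )
    return best_mat, best_val


def _function_id(a: int) -> str:
    """Deterministic function label; even indices KO, odd COG, so the
    merged KEGG-COG namespace is exercised without collisions."""
    return f"K{a:05d}" if a % 2 == 0 else f"COG{a:04d}"


def _lineage_for(genus: str) -> tuple[tuple[str, str], ...]:
    return (
        ("superkingdom", "Bacteria"),
        ("phylum", f"P_{genus}"),
        ("class", f"C_{genus}"),
        ("order", f"O_{genus}"),
        ("family", f"F_{genus}"),
        ("genus", genus),
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate per-sample peptide/protein/gene tables.

    Guarantees (checked by construction): the PCN built from any
    sample's tables has the designed support, a subset of the paired
    GCN's support, and NODF within 0.1 of ``spec.nestedness_target``;
    identical spec and seed give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    S, F = spec.n_taxa, spec.n_functions

    if spec.nestedness_target >= 0.999:
        if S != F:
            raise InfeasibleError(
                "NODF = 1 requires a square full staircase (n_taxa == n_functions)"
            )
        pcn_support = np.zeros((S, S), dtype=bool)
        for i in range(S):
            pcn_support[i, : S - i] = True
        realized = 1.0
    else:
        base = _nested_support(S, F, spec.pcn_connectance)
        pcn_support, realized = _calibrate_support(base, spec.nestedness_target, spec.seed)

    n_pcn = int(pcn_support.sum())
    n_gcn = min(S * F, round(n_pcn / spec.pcn_fraction_of_gcn))
    gcn_support = pcn_support.copy()
    free_i, free_a = np.nonzero(~pcn_support)
    extra = n_gcn - n_pcn
    if extra > 0:
        pick = rng.choice(free_i.size, size=min(extra, free_i.size), replace=False)
        gcn_support[free_i[pick], free_a[pick]] = True

    taxa = [f"Genus{i:03d}" for i in range(S)]
    functions = [_function_id(a) for a in range(F)]

    # base (pre-noise) weights and biomass
    if spec.weight_distribution == "lognormal":
        base_w = np.where(pcn_support, rng.lognormal(0.0, 1.0, (S, F)), 0.0)
    else:
        base_w = np.where(pcn_support, rng.uniform(0.2, 1.0, (S, F)), 0.0)
    base_biomass = rng.lognormal(0.0, 1.0, S)
    gene_base = np.where(gcn_support, rng.lognormal(3.0, 1.0, (S, F)), 0.0)

    effect_block = np.zeros(F, dtype=bool)
    if spec.group_effect is not None:
        effect_block[rng.choice(F, size=max(1, F // 5), replace=False)] = True

    samples = []
    for s in range(spec.n_samples):
        group = "control" if s < (spec.n_samples + 1) // 2 else "case"
        w = base_w * rng.lognormal(0.0, spec.noise_sigma, (S, F))
        w[~pcn_support] = 0.0
        if spec.group_effect is not None and group == "case":
            w[:, effect_block] *= 2.0 ** spec.group_effect
        biomass = base_biomass * rng.lognormal(0.0, spec.noise_sigma, S)
        biomass /= biomass.sum()
        row_tot = w.sum(axis=1, keepdims=True)
        intensities = biomass[:, None] * w / row_tot * 1e9  # taxon total ∝ biomass

        peptides: list[PeptideRecord] = []
        proteins: list[ProteinGroupRecord] = []
        n_pg = 0
        for i in range(S):
            for a in np.nonzero(pcn_support[i])[0]:
                pg_id = f"PG{n_pg:05d}"
                pep_id = f"pep{n_pg:05d}"
                intensity = float(intensities[i, a])
                peptides.append(
                    PeptideRecord(pep_id, f"SEQ{n_pg:05d}", intensity, True, _lineage_for(taxa[i]))
                )
                fn = functions[a]
                proteins.append(
                    ProteinGroupRecord(
                        pg_id,
                        frozenset([pep_id]),
                        intensity,
                        ko=fn if fn.startswith("K") else None,
                        cog=fn if fn.startswith("COG") else None,
                    )
                )
                n_pg += 1
        # a few unresolved peptides: shared (non-unique) and above-genus
        for extra_id in range(3):
            peptides.append(
                PeptideRecord(
                    f"shared{extra_id}", f"SHSEQ{extra_id}",
                    float(rng.lognormal(0.0, 1.0)), False, (),
                )
            )
            peptides.append(
                PeptideRecord(
                    f"family{extra_id}", f"FASEQ{extra_id}",
                    float(rng.lognormal(0.0, 1.0)), True,
                    (("superkingdom", "Bacteria"), ("phylum", "PX"), ("family", "FX")),
                )
            )

        counts = rng.poisson(gene_base) + gcn_support.astype(int)  # keep support exact
        genes = [
            GeneRecord(f"gene{i:03d}_{a:04d}", taxa[i], functions[a], int(counts[i, a]))
            for i in range(S)
            for a in np.nonzero(gcn_support[i])[0]
        ]
        samples.append(SampleTables(f"sample{s:02d}", group, peptides, proteins, genes))

    manifest = {
        "spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__},
        "n_pcn_edges": n_pcn,
        "n_gcn_edges": int(gcn_support.sum()),
        "realized_nodf": realized,
    }
    return SyntheticDataset(samples, pcn_support, gcn_support, taxa, functions, realized, manifest)


@dataclass(frozen=True)
class StrainProteome:
    """Row-normalized function weights of one cultured strain."""

    strain_id: str
    condition: str
    functions: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if len(self.functions) != w.size:
            raise ValidationError("functions/weights length mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be non-negative and sum to 1")


def simulate_strain_proteomes(
    strain_ids: list[str],
    conditions: list[str],
    n_functions: int = 40,
    seed: int = 0,
) -> dict[tuple[str, str], StrainProteome]:
    """Synthetic stand-ins for cultured single-strain proteomes.

    Each strain has a lognormal base expression profile over a core block
    shared by all strains plus a strain-specific block; each non-basal
    condition multiplies a condition-specific block of functions and adds
    lognormal noise, emulating medium-induced proteome shifts.
    """
    rng = np.random.default_rng(seed)
    functions = tuple(_function_id(a) for a in range(n_functions))
    core = n_functions // 2
    out: dict[tuple[str, str], StrainProteome] = {}
    cond_blocks = {
        c: rng.choice(n_functions, size=max(1, n_functions // 6), replace=False)
        for c in conditions
    }
    for k, sid in enumerate(strain_ids):
        base = np.zeros(n_functions)
        base[:core] = rng.lognormal(0.0, 1.0, core)
        own = core + (np.arange(n_functions - core) + k) % (n_functions - core)
        picked = rng.choice(own, size=max(1, (n_functions - core) // 2), replace=False)
        base[picked] = rng.lognormal(0.0, 1.0, picked.size)
        for c_idx, cond in enumerate(conditions):
            w = base * rng.lognormal(0.0, 0.2, n_functions)
            if c_idx > 0:
                w[cond_blocks[cond]] *= rng.lognormal(1.0, 0.5, cond_blocks[cond].size)
            w[base == 0] = 0.0
            w /= w.sum()
            out[(sid, cond)] = StrainProteome(sid, cond, functions, tuple(w))
    return out


def assemble_insilico_community(
    proteomes: list[StrainProteome], abundances: np.ndarray
) -> tuple[TaxonFunctionNetwork, AbundanceProfile]:
    """Stack strain proteomes into a community network at given abundances.

    Taxa are the strains; the function universe is the union of the
    strains' function lists; the abundance profile is the given
    proportions.
    """
    abundances = np.asarray(abundances, dtype=float)
    if abundances.shape != (len(proteomes),):
        raise ValidationError("abundances length must match proteomes")
    if np.any(abundances <= 0) or abs(abundances.sum() - 1.0) > 1e-9:
        raise ValidationError("abundances must be positive and sum to 1")
    functions = sorted({f for p in proteomes for f in p.functions})
    fi = {f: i for i, f in enumerate(functions)}
    weights = np.zeros((len(proteomes), len(functions)))
    taxa = []
    for i, p in enumerate(proteomes):
        label = f"{p.strain_id}|{p.condition}|{i}"
        taxa.append(label)
        for f, w in zip(p.functions, p.weights):
            weights[i, fi[f]] = w
    net = TaxonFunctionNetwork(taxa, functions, weights, "pcn")
    return net, AbundanceProfile(taxa, abundances)
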