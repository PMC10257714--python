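import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from proteofr.datatypes import (
    AbundanceProfile,
    PeptideRecord,
    ProteinGroupRecord,
    TaxonFunctionNetwork,
)
from proteofr.synthetic import SyntheticSpec, generate_dataset


def lineage(genus: str) -> tuple[tuple[str, str], ...]:
    return (("superkingdom", "Bacteria"), ("genus", genus))


@pytest.fixture
def staircase_net() -> TaxonFunctionNetwork:
    """Perfectly nested 3x3 staircase (distinct fills in both axes)."""
    w = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    return TaxonFunctionNetwork(["A", "B", "C"], ["f1", "f2", "f3"], w)


@pytest.fixture
def toy_sample():
    """Two genera, two proteins each, with genus-resolved unique peptides."""
    peptides = [
        PeptideRecord("p1", "AAA", 30.0, True, lineage("Bacteroides")),
        PeptideRecord("p2", "CCC", 10.0, True, lineage("Blautia")),
        PeptideRecord("p3", "DDD", 20.0, True, lineage("Bacteroides")),
        PeptideRecord("p4", "EEE", 5.0, False, ()),
    ]
    groups = [
        ProteinGroupRecord("PG1", frozenset({"p1", "p2"}), 100.0, ko="K00001"),
        ProteinGroupRecord("PG2", frozenset({"p3"}), 50.0, cog="COG0002"),
    ]
    return peptides, groups


@pytest.fixture(scope="session")
def small_dataset():
    """Session-wide synthetic dataset at modest size for pipeline tests."""
    return generate_dataset(SyntheticSpec(n_taxa=15, n_functions=50,
                                          nestedness_target=0.4,
                                          pcn_connectance=0.2, n_samples=3,
                                          seed=11))


def random_network(rng: np.random.Generator, s: int, f: int,
                   density: float = 0.6) -> TaxonFunctionNetwork:
    """Random row-normalized network with no all-zero rows."""
    w = np.where(rng.random((s, f)) < density, rng.random((s, f)), 0.0)
    for i in range(s):
        if w[i].sum() == 0:
            w[i, rng.integers(f)] = rng.random() + 0.1
    w /= w.sum(axis=1, keepdims=True)
    return TaxonFunctionNetwork([f"t{i}" for i in range(s)],
                                [f"f{a}" for a in range(f)], w)


def random_profile(rng: np.random.Generator, taxa: list[str]) -> AbundanceProfile:
    p = rng.random(len(taxa)) + 0.05
    return AbundanceProfile(list(taxa), p / p.sum())
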