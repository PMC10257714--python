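from itertools import combinations

import numpy as np
import pytest
from scipy.stats import chisquare

from proteofr.datatypes import AbundanceProfile, TaxonFunctionNetwork
from proteofr.diversity import sample_summary
from proteofr.errors import ValidationError
from proteofr.nulls import NullSpec, null_fr_comparison, randomize
from proteofr.synthetic import SyntheticSpec, generate_dataset
from proteofr.network import build_gcn, build_pcn, biomass_profile


def net(b, kind="pcn"):
    b = np.asarray(b, dtype=float)
    return TaxonFunctionNetwork(
        [f"t{i}" for i in range(b.shape[0])],
        [f"f{a}" for a in range(b.shape[1])],
        b,
        kind,
    )


@pytest.fixture(scope="module")
def built_pair():
    ds = generate_dataset(SyntheticSpec(n_taxa=12, n_functions=40, nestedness_target=0.45,
                                        pcn_connectance=0.2, n_samples=1, seed=21))
    s = ds.samples[0]
    return build_pcn(s.proteins, s.peptides), build_gcn(s.genes), biomass_profile(s.peptides)


class TestNullSpec:
    def test_variant_implies_flags(self):
        flags = {
            "null1": (False, False),
            "null2": (True, False),
            "null3": (False, True),
            "null4": (True, True),
        }
        for variant, (td, fd) in flags.items():
            spec = NullSpec(variant)
            assert (spec.preserve_taxon_degree, spec.preserve_function_degree) == (td, fd)

    def test_permute_policy_needs_taxon_degrees(self):
        with pytest.raises(ValidationError):
            NullSpec("null1", weight_policy="permute")
        NullSpec("null2", weight_policy="permute")  # fine


class TestContracts:
    @pytest.mark.parametrize("variant", ["null1", "null2", "null3", "null4"])
    def test_edges_subset_of_gcn_and_counts(self, built_pair, variant):
        pcn, gcn, _ = built_pair
        reps = randomize(pcn, gcn, NullSpec(variant, n_replicates=5, seed=3))
        gcn_edges = gcn.edge_set()
        n_pcn = np.count_nonzero(pcn.weights)
        pcn_b = pcn.binary()
        for rep in reps:
            assert rep.edge_set() <= gcn_edges
            assert np.count_nonzero(rep.weights) == n_pcn
            rb = rep.binary()
            # align on shared taxa (replicates live on GCN label space)
            ti = {t: i for i, t in enumerate(rep.taxa)}
            if variant in ("null2", "null4"):
                for i, t in enumerate(pcn.taxa):
                    assert rb[ti[t]].sum() == pcn_b[i].sum()
            if variant in ("null3", "null4"):
                fi = {f: i for i, f in enumerate(rep.functions)}
                for a, f in enumerate(pcn.functions):
                    assert rb[:, fi[f]].sum() == pcn_b[:, a].sum()

    def test_same_seed_reproduces_replicates(self, built_pair):
        pcn, gcn, _ = built_pair
        a = randomize(pcn, gcn, NullSpec("null4", n_replicates=3, seed=9))
        b = randomize(pcn, gcn, NullSpec("null4", n_replicates=3, seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.weights, y.weights)

    def test_gcn_equals_pcn_forces_identity(self):
        pcn = net([[1, 1, 0], [0, 1, 1]]).row_normalized()
        gcn = net([[1, 1, 0], [0, 1, 1]], "gcn").row_normalized()
        for variant in ("null1", "null2", "null3", "null4"):
            (rep,) = randomize(pcn, gcn, NullSpec(variant, n_replicates=1, seed=0))
            np.testing.assert_array_equal(rep.binary(), pcn.binary())

    def test_uniform_weight_policy_is_row_stochastic(self, built_pair):
        pcn, gcn, _ = built_pair
        (rep,) = randomize(pcn, gcn, NullSpec("null1", n_replicates=1, seed=1))
        sums = rep.weights.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)

    def test_permute_weight_policy_preserves_row_multisets(self, built_pair):
        pcn, gcn, _ = built_pair
        (rep,) = randomize(
            pcn, gcn, NullSpec("null4", n_replicates=1, seed=1, weight_policy="permute")
        )
        ti = {t: i for i, t in enumerate(rep.taxa)}
        for i, t in enumerate(pcn.taxa):
            original = np.sort(pcn.weights[i][pcn.weights[i] > 0])
            permuted = np.sort(rep.weights[ti[t]][rep.weights[ti[t]] > 0])
            np.testing.assert_allclose(permuted, original)


class TestNull2Uniformity:
    def test_uniform_over_feasible_configurations(self):
        # taxon degrees 2 and 1; GCN degrees 3 and 2 -> C(3,2)*C(2,1) = 6 configs
        pcn = net([[1, 1, 0], [0, 1, 0]]).row_normalized()
        gcn = net([[1, 1, 1], [0, 1, 1]], "gcn").row_normalized()
        n = 10_000
        reps = randomize(pcn, gcn, NullSpec("null2", n_replicates=n, seed=123))
        feasible = []
        for row0 in combinations(range(3), 2):
            for row1 in [(1,), (2,)]:
                feasible.append((row0, row1))
        counts = dict.fromkeys(feasible, 0)
        for rep in reps:
            b = rep.binary()
            key = (tuple(np.nonzero(b[0])[0]), tuple(np.nonzero(b[1])[0]))
            counts[key] += 1
        assert sum(counts.values()) == n
        observed = np.array(list(counts.values()))
        assert chisquare(observed).pvalue > 1e-4  # no gross deviation from uniform


class TestNull4Mixing:
    def test_chain_visits_every_feasible_configuration(self):
        # 3x3 with row degrees (2,1,1) and column degrees (2,1,1) under a
        # full GCN: the feasible set is small enough to enumerate
        pcn = net([[1, 1, 0], [1, 0, 0], [0, 0, 1]]).row_normalized()
        gcn = net(np.ones((3, 3)), "gcn").row_normalized()
        reps = randomize(pcn, gcn, NullSpec("null4", n_replicates=400, seed=7))
        seen = {tuple(rep.binary().ravel()) for rep in reps}
        row_deg = pcn.binary().sum(axis=1)
        col_deg = pcn.binary().sum(axis=0)
        # brute-force enumeration of all binary matrices with these margins
        feasible = set()
        for bits in range(2 ** 9):
            m = np.array([(bits >> k) & 1 for k in range(9)]).reshape(3, 3)
            if (m.sum(axis=1) == row_deg).all() and (m.sum(axis=0) == col_deg).all():
                feasible.add(tuple(m.astype(bool).ravel()))
        assert seen == feasible


class TestFRComparison:
    def test_natural_row_matches_sample_summary(self, built_pair):
        pcn, gcn, profile = built_pair
        table = null_fr_comparison(pcn, gcn, profile, n_replicates=2, seed=5)
        natural = table[table["variant"] == "natural"].iloc[0]
        expected = sample_summary(pcn, profile)
        assert natural["fr"] == pytest.approx(expected.fr, abs=1e-12)
        assert natural["nfr"] == pytest.approx(expected.nfr, abs=1e-12)

    def test_nested_pcn_has_higher_fr_than_null4(self, built_pair):
        # permuted weights isolate the topology contribution: the same
        # per-taxon weight multisets on randomized (less nested) supports
        pcn, gcn, profile = built_pair
        table = null_fr_comparison(pcn, gcn, profile, variants=["null4"],
                                   n_replicates=10, seed=2,
                                   weight_policy="permute")
        natural_fr = table.loc[table["variant"] == "natural", "fr"].iloc[0]
        null_fr = table.loc[table["variant"] == "null4", "fr"].mean()
        assert null_fr < natural_fr

    def test_identical_pcn_gcn_gives_identical_metrics_across_variants(self):
        b = [[1, 1, 0], [1, 0, 1], [0, 1, 1]]
        pcn = net(b).row_normalized()
        gcn = net(b, "gcn").row_normalized()
        profile = AbundanceProfile(pcn.taxa, np.full(3, 1 / 3))
        table = null_fr_comparison(pcn, gcn, profile, n_replicates=3, seed=0)
        assert table["fr"].nunique() == 1
        assert table["nodf"].nunique() == 1
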