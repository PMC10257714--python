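import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proteofr.datatypes import AbundanceProfile, PeptideRecord, ProteinGroupRecord
from proteofr.errors import EmptyNetworkError, ValidationError
from proteofr.network import (
    biomass_profile,
    bridge_proteins_to_taxa,
    build_gcn,
    build_pcn,
    filter_top_biomass,
    merge_annotations,
)
from proteofr.datatypes import GeneRecord

from conftest import lineage


class TestMergeAnnotations:
    def test_ko_takes_precedence_over_cog(self):
        groups = [
            ProteinGroupRecord("a", frozenset({"p"}), 1.0, ko="K00001", cog="COG0001"),
            ProteinGroupRecord("b", frozenset({"p"}), 1.0, cog="COG0002"),
            ProteinGroupRecord("c", frozenset({"p"}), 1.0),
        ]
        merged = merge_annotations(groups)
        assert merged == {"a": "K00001", "b": "COG0002"}


class TestBridge:
    def test_single_genus_group_gets_full_intensity(self):
        peptides = [PeptideRecord("p1", "A", 30.0, True, lineage("Bacteroides"))]
        groups = [ProteinGroupRecord("PG", frozenset({"p1"}), 100.0, ko="K1")]
        (a,) = bridge_proteins_to_taxa(groups, peptides)
        assert (a.genus, a.assigned_intensity) == ("Bacteroides", 100.0)

    def test_proportional_split_between_genera(self):
        peptides = [
            PeptideRecord("p1", "A", 30.0, True, lineage("Bacteroides")),
            PeptideRecord("p2", "C", 10.0, True, lineage("Blautia")),
        ]
        groups = [ProteinGroupRecord("PG", frozenset({"p1", "p2"}), 100.0, ko="K1")]
        split = {a.genus: a.assigned_intensity for a in bridge_proteins_to_taxa(groups, peptides)}
        assert split == {"Bacteroides": 75.0, "Blautia": 25.0}  # 100*30/40, 100*10/40

    def test_above_genus_peptides_yield_no_assignment(self):
        peptides = [
            PeptideRecord(
                "p1", "A", 30.0, True,
                (("superkingdom", "Bacteria"), ("family", "Lachnospiraceae")),
            )
        ]
        groups = [ProteinGroupRecord("PG", frozenset({"p1"}), 100.0, ko="K1")]
        assert bridge_proteins_to_taxa(groups, peptides) == []

    def test_dangling_peptide_id_names_the_group(self):
        groups = [ProteinGroupRecord("PG9", frozenset({"ghost"}), 1.0, ko="K1")]
        with pytest.raises(ValidationError, match="PG9"):
            bridge_proteins_to_taxa(groups, [])

    def test_bridge_conserves_group_intensity(self, small_dataset):
        sample = small_dataset.samples[0]
        assignments = bridge_proteins_to_taxa(sample.proteins, sample.peptides)
        per_group: dict[str, float] = {}
        for a in assignments:
            per_group[a.group_id] = per_group.get(a.group_id, 0.0) + a.assigned_intensity
        totals = {g.group_id: g.intensity for g in sample.proteins}
        for gid, assigned in per_group.items():
            assert assigned == pytest.approx(totals[gid], rel=1e-12)


class TestBuildNetworks:
    def test_pcn_row_normalization_by_hand(self):
        peptides = [
            PeptideRecord("p1", "A", 1.0, True, lineage("G")),
            PeptideRecord("p2", "C", 1.0, True, lineage("G")),
        ]
        groups = [
            ProteinGroupRecord("a", frozenset({"p1"}), 30.0, ko="K1"),
            ProteinGroupRecord("b", frozenset({"p2"}), 70.0, ko="K2"),
        ]
        net = build_pcn(groups, peptides)
        assert net.taxa == ["G"]
        np.testing.assert_allclose(net.weights, [[0.3, 0.7]])

    def test_same_function_same_genus_aggregates(self):
        peptides = [PeptideRecord("p1", "A", 1.0, True, lineage("G"))]
        groups = [
            ProteinGroupRecord("a", frozenset({"p1"}), 30.0, ko="K1"),
            ProteinGroupRecord("b", frozenset({"p1"}), 20.0, ko="K1"),
            ProteinGroupRecord("c", frozenset({"p1"}), 50.0, ko="K2"),
        ]
        net = build_pcn(groups, peptides)
        np.testing.assert_allclose(net.weights, [[0.5, 0.5]])

    def test_all_unannotated_raises_empty_network(self, toy_sample):
        peptides, _ = toy_sample
        groups = [ProteinGroupRecord("x", frozenset({"p1"}), 5.0)]
        with pytest.raises(EmptyNetworkError):
            build_pcn(groups, peptides)

    def test_gcn_normalization_and_duplicate_rows(self):
        genes = [
            GeneRecord("g1", "T1", "F1", 5),
            GeneRecord("g2", "T1", "F1", 3),  # duplicate cell, summed
            GeneRecord("g3", "T1", "F2", 2),
            GeneRecord("g4", "T2", "F2", 0),  # all-zero taxon dropped
        ]
        net = build_gcn(genes)
        assert net.taxa == ["T1"]
        np.testing.assert_allclose(net.weights, [[0.8, 0.2]])

    def test_built_networks_are_row_stochastic(self, small_dataset):
        sample = small_dataset.samples[0]
        pcn = build_pcn(sample.proteins, sample.peptides)
        gcn = build_gcn(sample.genes)
        assert pcn.is_row_stochastic() and gcn.is_row_stochastic()
        assert np.all(pcn.weights.sum(axis=1) > 0)


class TestBiomass:
    def test_hand_normalization_and_unique_only(self):
        peptides = [
            PeptideRecord("p1", "A", 60.0, True, lineage("Bacteroides")),
            PeptideRecord("p2", "C", 40.0, True, lineage("Blautia")),
            PeptideRecord("p3", "D", 999.0, False, ()),  # non-unique excluded
        ]
        profile = biomass_profile(peptides)
        assert profile.taxa == ["Bacteroides", "Blautia"]
        np.testing.assert_allclose(profile.p, [0.6, 0.4])

    def test_single_genus(self):
        profile = biomass_profile([PeptideRecord("p", "A", 5.0, True, lineage("G"))])
        np.testing.assert_array_equal(profile.p, [1.0])

    def test_no_resolved_peptides_raises(self):
        with pytest.raises(ValidationError):
            biomass_profile([PeptideRecord("p", "A", 5.0, False, ())])


class TestTopBiomassFilter:
    def test_hand_cumulative_sums(self):
        profile = AbundanceProfile(["a", "b", "c"], np.array([0.6, 0.3, 0.1]))
        assert filter_top_biomass(profile, 0.95) == {"a", "b", "c"}
        profile2 = AbundanceProfile(["a", "b"], np.array([0.96, 0.04]))
        assert filter_top_biomass(profile2, 0.95) == {"a"}

    def test_fraction_one_keeps_all(self):
        profile = AbundanceProfile(["a", "b"], np.array([0.99, 0.01]))
        assert filter_top_biomass(profile, 1.0) == {"a", "b"}

    def test_boundary_ties_are_all_included(self):
        profile = AbundanceProfile(["a", "b", "c"], np.array([0.5, 0.25, 0.25]))
        assert filter_top_biomass(profile, 0.7) == {"a", "b", "c"}

    def test_invalid_fraction(self):
        profile = AbundanceProfile(["a"], np.array([1.0]))
        with pytest.raises(ValidationError):
            filter_top_biomass(profile, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        f1=st.floats(0.05, 1.0),
        f2=st.floats(0.05, 1.0),
    )
    def test_rank_monotonicity(self, p, f1, f2):
        arr = np.array(p) / np.sum(p)
        profile = AbundanceProfile([f"t{i}" for i in range(len(p))], arr)
        lo, hi = sorted([f1, f2])
        assert filter_top_biomass(profile, lo) <= filter_top_biomass(profile, hi)
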