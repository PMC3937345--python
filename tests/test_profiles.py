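"""Normalization, merging, collapsing and module profiling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from halocca.datamodel import AbundanceMatrix, ModuleMap
from halocca.profiles import (
    GenomeEquivalents,
    collapse_taxonomy,
    genome_equivalents_from_bp,
    merge_size_fractions,
    module_profile,
    normalize_by_genome_equivalents,
    relative_abundance,
    stratify_by_taxon,
)


def _matrix(values, samples, features, kind="taxon", state="raw_counts"):
    frame = pd.DataFrame(
        values, index=pd.Index(samples, name="sample_id"), columns=features, dtype=float
    )
    return AbundanceMatrix(frame, kind, state)


class TestGenomeEquivalents:
    @pytest.mark.parametrize(
        "total_bp,avg,expected",
        [
            (1.0e9, 2.5e6, 400.0),
            (3.0e6, 3.0e6, 1.0),
            (7.6e9, 3.0e6, 7.6e9 / 3.0e6),  # ~2533.33 genomes in a 7.6 Gbp dataset
        ],
    )
    def test_bp_over_genome_size(self, total_bp, avg, expected):
        assert genome_equivalents_from_bp(total_bp, avg) == pytest.approx(expected)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            genome_equivalents_from_bp(0.0, 2.5e6)
        with pytest.raises(ValueError):
            genome_equivalents_from_bp(1e9, -1.0)

    def test_normalization_divides_rows(self):
        m = _matrix([[100, 300], [10, 30]], ["GS1", "GS2"], ["A", "B"])
        ge = GenomeEquivalents(pd.Series({"GS1": 4.0, "GS2": 1.0}))
        out = normalize_by_genome_equivalents(m, ge)
        assert out.state == "genome_equivalent_normalized"
        assert list(out.frame.loc["GS1"]) == [25.0, 75.0]
        assert list(out.frame.loc["GS2"]) == [10.0, 30.0]

    def test_missing_sample_named(self):
        m = _matrix([[1, 2]], ["GS1"], ["A", "B"])
        ge = GenomeEquivalents(pd.Series({"GS9": 1.0}))
        with pytest.raises(KeyError, match="GS1"):
            normalize_by_genome_equivalents(m, ge)

    def test_scale_invariance(self):
        """Doubling a sample's counts and its GE leaves the normalized row fixed."""
        m1 = _matrix([[100, 300]], ["GS1"], ["A", "B"])
        m2 = _matrix([[200, 600]], ["GS1"], ["A", "B"])
        out1 = normalize_by_genome_equivalents(m1, GenomeEquivalents(pd.Series({"GS1": 4.0})))
        out2 = normalize_by_genome_equivalents(m2, GenomeEquivalents(pd.Series({"GS1": 8.0})))
        pd.testing.assert_frame_equal(out1.frame, out2.frame)

    def test_commutes_with_relative_abundance(self):
        """Proportions are invariant to genome-equivalent scaling per sample."""
        m = _matrix([[10, 30, 60], [5, 5, 10]], ["GS1", "GS2"], ["A", "B", "C"])
        ge = GenomeEquivalents(pd.Series({"GS1": 7.0, "GS2": 3.0}))
        direct = relative_abundance(m)
        via_ge = relative_abundance(normalize_by_genome_equivalents(m, ge))
        pd.testing.assert_frame_equal(direct.frame, via_ge.frame)


class TestMergeSizeFractions:
    KEYS = {"GS1_a": ("TT", 5.0), "GS1_b": ("TT", 5.0), "GS1_c": ("TT", 5.0)}

    def test_two_fractions_sum(self):
        m1 = _matrix([[1, 2]], ["GS1_a"], ["A", "B"])
        m2 = _matrix([[3, 4]], ["GS1_b"], ["A", "B"])
        out = merge_size_fractions([m1, m2], self.KEYS)
        assert list(out.frame.loc["TT_5"]) == [4.0, 6.0]

    def test_single_fraction_renames_only(self):
        m = _matrix([[1, 2]], ["GS1_a"], ["A", "B"])
        out = merge_size_fractions([m], self.KEYS)
        assert out.samples == ["TT_5"]
        assert list(out.frame.loc["TT_5"]) == [1.0, 2.0]

    def test_three_fractions_match_brute_force(self, rng):
        mats = [
            _matrix(rng.integers(0, 50, size=(1, 4)), [s], ["A", "B", "C", "D"])
            for s in self.KEYS
        ]
        out = merge_size_fractions(mats, self.KEYS)
        brute = np.zeros(4)
        for m in mats:
            for j, f in enumerate(["A", "B", "C", "D"]):
                brute[j] += m.frame.iloc[0][f]
        assert np.array_equal(out.frame.loc["TT_5"].to_numpy(), brute)

    def test_mixed_states_rejected(self):
        m1 = _matrix([[1, 2]], ["GS1_a"], ["A", "B"])
        m2 = _matrix([[0.5, 0.5]], ["GS1_b"], ["A", "B"], state="proportions")
        with pytest.raises(ValueError, match="raw counts"):
            merge_size_fractions([m1, m2], self.KEYS)


class TestCollapseTaxonomy:
    def test_same_phylum_sums(self, small_lineage):
        m = _matrix([[5, 7]], ["GS1"], ["Limnoluna", "Nanopelagicus"])
        out = collapse_taxonomy(m, small_lineage, "phylum")
        assert out.frame.loc["GS1", "Actinobacteria"] == 12.0

    def test_collapse_at_own_rank_is_permutation(self, small_lineage):
        m = _matrix([[1, 2, 3]], ["GS1"], ["Pelagibacter", "Alteromonas", "Limnoluna"])
        out = collapse_taxonomy(m, small_lineage, "genus")
        assert sorted(out.frame.loc["GS1"]) == [1.0, 2.0, 3.0]
        assert set(out.features) == {"Pelagibacter", "Alteromonas", "Limnoluna"}

    def test_unknown_taxon_pools_into_unclassified(self, small_lineage):
        m = _matrix([[4, 6]], ["GS1"], ["Pelagibacter", "MysteryBug"])
        out = collapse_taxonomy(m, small_lineage, "phylum")
        assert out.frame.loc["GS1", "unclassified"] == 6.0

    def test_topk_with_other_conserves_row_sums(self, small_lineage, rng):
        counts = rng.integers(0, 100, size=(3, 4))
        m = _matrix(
            counts,
            ["GS1", "GS2", "GS3"],
            ["Pelagibacter", "Alteromonas", "Limnoluna", "Nanopelagicus"],
        )
        out = collapse_taxonomy(m, small_lineage, "genus", top=2)
        assert "Other" in out.features
        assert np.array_equal(
            out.frame.sum(axis=1).to_numpy(), counts.sum(axis=1).astype(float)
        )

    def test_unknown_rank_rejected(self, small_lineage):
        m = _matrix([[1]], ["GS1"], ["Pelagibacter"])
        with pytest.raises(ValueError, match="rank"):
            collapse_taxonomy(m, small_lineage, "domain")


class TestModuleProfile:
    def test_mean_over_member_kos(self, counts_2x2, small_module_map):
        # M1 = {K00001, K00002}: GS1 -> (100+0)/2
        out = module_profile(counts_2x2, small_module_map)
        assert out.frame.loc["GS1", "M1"] == 50.0
        assert out.frame.loc["GS2", "M1"] == 200.0

    def test_absent_ko_counts_as_zero(self, counts_2x2, small_module_map):
        # M2 = {K00002, K00003}; K00003 missing from the matrix
        out = module_profile(counts_2x2, small_module_map)
        assert out.frame.loc["GS2", "M2"] == 50.0

    def test_single_ko_module_is_identity(self, counts_2x2):
        mmap = ModuleMap.from_pairs([("K00001", "M9")])
        out = module_profile(counts_2x2, mmap)
        pd.testing.assert_series_equal(
            out.frame["M9"], counts_2x2.frame["K00001"], check_names=False
        )

    def test_no_shared_ko_rejected(self, counts_2x2):
        mmap = ModuleMap.from_pairs([("K99999", "M9")])
        with pytest.raises(ValueError, match="no KO"):
            module_profile(counts_2x2, mmap)

    def test_matches_brute_force_means(self, rng):
        kos = [f"K{i:05d}" for i in range(12)]
        m = _matrix(rng.random((6, 12)) * 100, [f"S{i}" for i in range(6)], kos, kind="ko")
        pairs = []
        for mod in range(5):
            members = rng.choice(kos + ["K99991", "K99992"], size=3, replace=False)
            pairs.extend((ko, f"M{mod}") for ko in members)
        mmap = ModuleMap.from_pairs(pairs)
        out = module_profile(m, mmap)
        for mod in mmap.modules:
            members = mmap.members(mod)
            for s in m.samples:
                expected = (
                    sum(m.frame.at[s, ko] for ko in members if ko in m.features)
                    / len(members)
                )
                assert out.frame.at[s, mod] == pytest.approx(expected, abs=1e-12)

    def test_linearity(self, counts_2x2, small_module_map):
        doubled = AbundanceMatrix(counts_2x2.frame * 2, "ko", "raw_counts")
        out1 = module_profile(counts_2x2, small_module_map)
        out2 = module_profile(doubled, small_module_map)
        pd.testing.assert_frame_equal(out2.frame, out1.frame * 2)


class TestStratifyByTaxon:
    @pytest.fixture
    def annotations(self):
        rows = []
        for s in ["GS1", "GS2"]:
            rows += [
                (s, "Pelagibacter", "K00001", 10),
                (s, "Pelagibacter", "K00002", 4),
                (s, "Limnoluna", "K00001", 6),
                (s, "Limnoluna", "K00003", 2),
            ]
        return pd.DataFrame(rows, columns=["sample_id", "taxon", "KO", "count"])

    def test_only_matching_phylum_contributes(self, annotations, small_lineage, small_module_map):
        out = stratify_by_taxon(annotations, small_lineage, "Proteobacteria", small_module_map)
        # Pelagibacter only: M1 = (10 + 4) / 2
        assert out.frame.loc["GS1", "M1"] == 7.0

    def test_root_equals_unstratified(self, annotations, small_lineage, small_module_map):
        out = stratify_by_taxon(annotations, small_lineage, "root", small_module_map)
        ko = annotations.pivot_table(
            index="sample_id", columns="KO", values="count", aggfunc="sum"
        ).fillna(0.0)
        unstrat = module_profile(
            AbundanceMatrix(ko, "ko", "raw_counts"), small_module_map
        )
        pd.testing.assert_frame_equal(out.frame, unstrat.frame)

    def test_matches_brute_force_filter_and_sum(self, small_lineage, small_module_map, rng):
        taxa = ["Pelagibacter", "Alteromonas", "Limnoluna", "Nanopelagicus"]
        kos = ["K00001", "K00002", "K00003"]
        rows = [
            (f"GS{i}", t, k, int(rng.integers(0, 20)))
            for i in range(2)
            for t in taxa
            for k in kos
        ][:20]
        ann = pd.DataFrame(rows, columns=["sample_id", "taxon", "KO", "count"])
        out = stratify_by_taxon(ann, small_lineage, "Actinobacteria", small_module_map)
        keep = {"Limnoluna", "Nanopelagicus"}
        for s in out.samples:
            sub = ann[(ann["sample_id"] == s) & (ann["taxon"].isin(keep))]
            by_ko = sub.groupby("KO")["count"].sum()
            expected = (by_ko.get("K00001", 0) + by_ko.get("K00002", 0)) / 2
            assert out.frame.at[s, "M1"] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_stratum_rejected(self, annotations, small_lineage, small_module_map):
        ann = annotations[annotations["taxon"] == "Pelagibacter"].copy()
        ann["count"] = 0
        with pytest.raises(ValueError, match="zero reads"):
            stratify_by_taxon(ann, small_lineage, "Proteobacteria", small_module_map)

    def test_mostly_empty_stratum_warns(self, small_lineage, small_module_map):
        rows = [
            ("GS1", "Limnoluna", "K00001", 5),
            ("GS1", "Pelagibacter", "K00001", 5),
            ("GS2", "Pelagibacter", "K00001", 5),
            ("GS3", "Pelagibacter", "K00001", 5),
        ]
        ann = pd.DataFrame(rows, columns=["sample_id", "taxon", "KO", "count"])
        with pytest.warns(UserWarning, match="zero reads"):
            stratify_by_taxon(ann, small_lineage, "Actinobacteria", small_module_map)


class TestRelativeAbundance:
    def test_halves(self):
        m = _matrix([[2, 2]], ["GS1"], ["A", "B"])
        out = relative_abundance(m)
        assert list(out.frame.loc["GS1"]) == [0.5, 0.5]
        assert out.state == "proportions"

    def test_single_column_all_ones(self):
        m = _matrix([[3], [7]], ["GS1", "GS2"], ["A"])
        out = relative_abundance(m)
        assert list(out.frame["A"]) == [1.0, 1.0]

    def test_zero_row_names_sample(self):
        m = _matrix([[1, 1], [0, 0]], ["GS1", "GS2"], ["A", "B"])
        with pytest.raises(ValueError, match="GS2"):
            relative_abundance(m)

    @given(
        st.lists(
            st.lists(st.floats(min_value=0, max_value=1e6), min_size=4, max_size=4).filter(
                lambda row: sum(row) > 1e-6
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_rows_sum_to_one(self, values):
        m = _matrix(values, [f"S{i}" for i in range(len(values))], list("ABCD"))
        out = relative_abundance(m)
        assert np.allclose(out.frame.sum(axis=1), 1.0, atol=1e-12)


class TestConservation:
    def test_integer_counts_stay_integer_through_merge_and_collapse(
        self, small_lineage, rng
    ):
        counts = rng.integers(0, 1000, size=(2, 4))
        taxa = ["Pelagibacter", "Alteromonas", "Limnoluna", "Nanopelagicus"]
        m1 = _matrix(counts[:1], ["GS1_a"], taxa)
        m2 = _matrix(counts[1:], ["GS1_b"], taxa)
        merged = merge_size_fractions(
            [m1, m2], {"GS1_a": ("TT", 5.0), "GS1_b": ("TT", 5.0)}
        )
        collapsed = collapse_taxonomy(merged, small_lineage, "phylum")
        total = collapsed.frame.to_numpy().sum()
        assert total == counts.sum()
        assert float(total).is_integer()
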