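import numpy as np
import pytest

from helpers import build_tax, lca_oracle, make_ra, random_taxonomy
from lcabin.alignment_io import RefClassMap
from lcabin.binning import (
    UNASSIGNED,
    UNRESOLVED,
    ReadAssignment,
    RefWeights,
    assignments_to_counts,
    compute_ref_weights,
    functional_bin,
    min_support_filter,
    naive_lca,
    project_to_rank,
    weighted_lca,
)
from lcabin.classification import load_hierarchy


def table_map(mapping):
    return RefClassMap(mode="numeric-id-table", table=dict(mapping))


@pytest.fixture
def genus_tax():
    """root(1) -> G(2, genus) -> {s1(3), s2(4)} species."""
    return build_tax(
        [
            (1, 1, "root", "root"),
            (2, 1, "genus", "G"),
            (3, 2, "species", "s1"),
            (4, 2, "species", "s2"),
        ]
    )


class TestNaiveLca:
    def test_singleton_species(self, genus_tax):
        ra = make_ra("r", [("refA", 90.0), ("refB", 80.0)])
        a = naive_lca(ra, genus_tax, table_map({"refA": 3, "refB": 3}))
        assert a.class_id == 3 and a.algorithm == "naive-lca"

    def test_two_species_meet_at_genus(self, genus_tax):
        ra = make_ra("r", [("refA", 90.0), ("refB", 80.0)])
        a = naive_lca(ra, genus_tax, table_map({"refA": 3, "refB": 4}))
        assert a.class_id == 2

    def test_unresolvable_reads_are_unassigned(self, genus_tax):
        ra = make_ra("r", [("refX", 90.0)])
        assert naive_lca(ra, genus_tax, table_map({})).class_id == UNASSIGNED

    def test_taxon_missing_from_taxonomy_is_skipped(self, genus_tax):
        ra = make_ra("r", [("refA", 90.0), ("refB", 80.0)])
        a = naive_lca(ra, genus_tax, table_map({"refA": 3, "refB": 999}))
        assert a.class_id == 3

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            tax = random_taxonomy(rng, int(rng.integers(2, 120)))
            taxa = rng.choice(list(tax.nodes), size=int(rng.integers(1, 5)))
            mapping = {f"ref{i}": int(t) for i, t in enumerate(taxa)}
            ra = make_ra("r", [(ref, 100.0 - i) for i, ref in enumerate(mapping)])
            got = naive_lca(ra, tax, table_map(mapping)).class_id
            assert got == lca_oracle(tax, set(mapping.values()))


class TestRefWeights:
    def test_unique_alignment_increments(self, genus_tax):
        reads = [make_ra("r1", [("refA", 90.0)])]
        rw = compute_ref_weights(iter(reads), genus_tax, table_map({"refA": 3}))
        assert rw.weights["refA"] == 1
        # floor is not double-applied on top of a real count
        reads = [make_ra(f"r{i}", [("refA", 90.0)]) for i in range(3)]
        rw = compute_ref_weights(iter(reads), genus_tax, table_map({"refA": 3}))
        assert rw.weights["refA"] == 3

    def test_same_species_references_share_credit(self, genus_tax):
        m = table_map({"refA": 3, "refA2": 3})
        reads = [make_ra("r1", [("refA", 90.0), ("refA2", 85.0)])]
        rw = compute_ref_weights(iter(reads), genus_tax, m)
        assert rw.weights == {"refA": 1, "refA2": 1}

    def test_cross_species_read_contributes_nothing_but_floor_applies(self, genus_tax):
        m = table_map({"refA": 3, "refB": 4})
        reads = [
            make_ra("r1", [("refA", 90.0), ("refB", 85.0)]),  # spans 2 species
            make_ra("r2", [("refA", 90.0)]),
            make_ra("r3", [("refA", 88.0)]),
        ]
        rw = compute_ref_weights(iter(reads), genus_tax, m)
        assert rw.weights["refA"] == 2  # r2, r3
        assert rw.weights["refB"] == 1  # floor

    def test_species_fallback_when_no_species_ancestor(self):
        tax = build_tax([(1, 1, "root", "root"), (2, 1, "genus", "G")])
        reads = [make_ra("r1", [("refG", 90.0)])]
        rw = compute_ref_weights(iter(reads), tax, table_map({"refG": 2}))
        assert rw.species_of["refG"] == 2 and rw.weights["refG"] == 1


class TestWeightedLca:
    def test_dominant_species_wins(self, genus_tax):
        m = table_map({"refA": 3, "refB": 4})
        rw = RefWeights(weights={"refA": 9, "refB": 1})
        ra = make_ra("r", [("refA", 90.0), ("refB", 85.0)])
        assert weighted_lca(ra, rw, genus_tax, m, coverage=0.75).class_id == 3

    def test_split_weight_lands_on_genus(self, genus_tax):
        m = table_map({"refA": 3, "refB": 4})
        rw = RefWeights(weights={"refA": 6, "refB": 4})
        ra = make_ra("r", [("refA", 90.0), ("refB", 85.0)])
        assert weighted_lca(ra, rw, genus_tax, m, coverage=0.75).class_id == 2

    def test_single_reference_ignores_coverage(self, genus_tax):
        m = table_map({"refA": 3})
        rw = RefWeights(weights={"refA": 1})
        ra = make_ra("r", [("refA", 90.0)])
        assert weighted_lca(ra, rw, genus_tax, m, coverage=0.99).class_id == 3

    def test_coverage_below_half_rejected(self, genus_tax):
        ra = make_ra("r", [("refA", 90.0)])
        with pytest.raises(ValueError):
            weighted_lca(ra, RefWeights(), genus_tax, table_map({"refA": 3}), coverage=0.5)

    def test_high_coverage_single_species_reads_match_naive(self, genus_tax):
        # reads resolving to a single species: weighted(cov->1) == naive
        m = table_map({"refA": 3, "refA2": 3})
        rw = RefWeights(weights={"refA": 5, "refA2": 2})
        ra = make_ra("r", [("refA", 90.0), ("refA2", 85.0)])
        w = weighted_lca(ra, rw, genus_tax, m, coverage=0.999999)
        assert w.class_id == naive_lca(ra, genus_tax, m).class_id


class TestMinSupport:
    def test_threshold_one_is_identity(self, genus_tax):
        a = [ReadAssignment("r1", 3, "naive-lca")]
        out = min_support_filter(a, genus_tax, min_support=1)
        assert out[0].class_id == 3

    def test_single_promotion(self, genus_tax):
        assignments = [ReadAssignment(f"r{i}", 3, "naive-lca") for i in range(2)]
        assignments += [ReadAssignment(f"g{i}", 2, "naive-lca") for i in range(10)]
        out = min_support_filter(assignments, genus_tax, min_support=3)
        counts = assignments_to_counts(out)
        assert counts == {2: 12}

    def test_cascading_promotion(self, ladder_tax):
        # 2 reads at strain(5), threshold 3, nothing else until phylum carries mass
        assignments = [ReadAssignment(f"r{i}", 5, "naive-lca") for i in range(2)]
        assignments += [ReadAssignment(f"p{i}", 2, "naive-lca") for i in range(5)]
        out = min_support_filter(assignments, ladder_tax, min_support=3)
        counts = assignments_to_counts(out)
        assert counts == {2: 7}

    def test_reapplication_is_identity(self, genus_tax):
        assignments = [ReadAssignment(f"r{i}", 3, "naive-lca") for i in range(2)]
        assignments += [ReadAssignment(f"g{i}", 2, "naive-lca") for i in range(10)]
        once = min_support_filter(assignments, genus_tax, min_support=3)
        snapshot = assignments_to_counts(once)
        twice = min_support_filter(once, genus_tax, min_support=3)
        assert assignments_to_counts(twice) == snapshot


class TestProjection:
    def test_worked_apportionment_example(self):
        # 10 reads at t; children subtree counts {c1: 30, c2: 10} -> {8, 2}
        tax = build_tax(
            [
                (1, 1, "root", "root"),
                (2, 1, "phylum", "t"),
                (3, 2, "genus", "c1"),
                (4, 2, "genus", "c2"),
            ]
        )
        profile = project_to_rank({2: 10, 3: 30, 4: 10}, tax, "genus")
        assert profile.counts == {3: 38, 4: 12}

    def test_identity_when_all_reads_at_rank(self, genus_tax):
        profile = project_to_rank({3: 5, 4: 7}, genus_tax, "species")
        assert profile.counts == {3: 5, 4: 7}

    def test_rollup_from_below(self, ladder_tax):
        profile = project_to_rank({5: 4}, ladder_tax, "species")
        assert profile.counts == {4: 4}

    def test_dead_end_goes_to_unresolved(self):
        tax = build_tax([(1, 1, "root", "root"), (2, 1, "phylum", "P")])
        profile = project_to_rank({2: 6}, tax, "species")
        assert profile.counts == {UNRESOLVED: 6}

    def test_unknown_rank_rejected(self, genus_tax):
        with pytest.raises(ValueError):
            project_to_rank({3: 1}, genus_tax, "tribe")

    def test_exact_conservation_on_random_configurations(self):
        rng = np.random.default_rng(11)
        from lcabin.taxonomy import RANKS

        for _ in range(60):
            tax = random_taxonomy(rng, int(rng.integers(2, 100)))
            nodes = list(tax.nodes)
            chosen = rng.choice(nodes, size=min(len(nodes), 10))
            counts = {int(t): int(rng.integers(0, 50)) for t in chosen}
            rank = RANKS[int(rng.integers(1, len(RANKS)))]
            profile = project_to_rank(counts, tax, rank)
            assert sum(profile.counts.values()) == sum(counts.values())


class TestFunctionalBin:
    TREE = "ROOT_NODE\tROOT\troot\nSS1\tROOT_NODE\tsubsystem\nR1\tSS1\trole 1\nR2\tSS1\trole 2\n"

    def test_first_resolvable_wins(self):
        tree = load_hierarchy(self.TREE)
        m = RefClassMap(mode="numeric-id-table", table={"c": "R1"})
        ra = make_ra("r", [("a", 90.0), ("b", 85.0), ("c", 80.0)])
        a = functional_bin(ra, m, tree)
        assert a.class_id == "R1" and a.algorithm == "best-hit"

    def test_tie_broken_by_input_order(self):
        tree = load_hierarchy(self.TREE)
        m = RefClassMap(mode="numeric-id-table", table={"a": "R1", "b": "R2"})
        ra = make_ra("r", [("a", 90.0), ("b", 90.0)])
        assert functional_bin(ra, m, tree).class_id == "R1"

    def test_inner_node_assignment_is_legal(self):
        tree = load_hierarchy(self.TREE)
        m = RefClassMap(mode="numeric-id-table", table={"a": "SS1"})
        assert functional_bin(make_ra("r", [("a", 9.0)]), m, tree).class_id == "SS1"

    def test_unassigned_when_nothing_resolves(self):
        tree = load_hierarchy(self.TREE)
        m = RefClassMap(mode="numeric-id-table", table={})
        assert functional_bin(make_ra("r", [("a", 9.0)]), m, tree).class_id == UNASSIGNED
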