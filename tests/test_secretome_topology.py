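"""Signed regulation vectors, distances, overlaps and network tables."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from glycosecretome.differential_stats import DifferentialRecord
from glycosecretome.secretome_topology import (
    SignedGroupVector,
    build_signed_vectors,
    euclidean_distance_matrix,
    glycan_protein_network,
    glycans_per_site,
    intersect_datasets,
    network_graph,
    overlap_fraction,
    sites_per_protein,
)


def rec(protein, site, comp, direction):
    significant = direction in ("up", "down")
    return DifferentialRecord(
        (protein, site, comp), 1.0 if direction == "up" else -1.0,
        0.01 if significant else 0.5, significant, direction)


def vec(entries, dataset="D", category="vesicle", dims=None):
    dims = tuple(range(len(entries))) if dims is None else dims
    return SignedGroupVector(dataset, category, dims, np.array(entries))


class TestBuildSignedVectors:
    ASSIGNMENT = {"P1": {"vesicle"}, "P2": {"lysosome"}, "P3": {"vesicle", "lysosome"}}

    def test_entries_follow_significance_membership_and_direction(self):
        diff = {
            "A": [rec("P1", 1, "c1", "up"), rec("P2", 2, "c2", "down"),
                  rec("P3", 3, "c3", "none")],
            "B": [rec("P1", 1, "c1", "none"), rec("P3", 3, "c3", "up")],
        }
        vectors = {(v.dataset, v.category): v for v in build_signed_vectors(
            diff, self.ASSIGNMENT, ["vesicle", "lysosome"])}
        dims = vectors[("A", "vesicle")].dims
        assert set(dims) == {("P1", 1, "c1"), ("P2", 2, "c2"), ("P3", 3, "c3")}
        i1, i2, i3 = (dims.index(k) for k in
                      [("P1", 1, "c1"), ("P2", 2, "c2"), ("P3", 3, "c3")])
        a_ves = vectors[("A", "vesicle")].entries
        assert a_ves[i1] == 1          # up-significant, protein in vesicle
        assert a_ves[i2] == 0          # protein not in vesicle
        assert a_ves[i3] == 0          # not significant in A
        assert vectors[("A", "lysosome")].entries[i2] == -1
        assert (vectors[("B", "vesicle")].entries[i1] == 0)  # not significant in B
        assert vectors[("B", "lysosome")].entries[i3] == 1

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            build_signed_vectors({}, {}, ["mitochondrion"])


class TestEuclideanDistanceMatrix:
    def test_worked_example(self):
        u, v = vec([1, 0, -1]), vec([1, 1, 0], dataset="E")
        matrix = euclidean_distance_matrix([u, v])
        assert matrix.iloc[0, 1] == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert matrix.iloc[0, 0] == 0.0

    def test_opposite_regulation(self):
        matrix = euclidean_distance_matrix([vec([1]), vec([-1], dataset="E")])
        assert matrix.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self, rng):
        vectors = [vec(rng.choice([-1, 0, 1], size=500), dataset=f"D{i}")
                   for i in range(8)]
        matrix = euclidean_distance_matrix(vectors).to_numpy()
        for i in range(8):
            for j in range(8):
                expected = np.sqrt(np.sum(
                    (vectors[i].entries.astype(float)
                     - vectors[j].entries.astype(float)) ** 2))
                assert abs(matrix[i, j] - expected) < 1e-12
        assert np.allclose(matrix, matrix.T)
        assert np.all(np.diag(matrix) == 0)

    def test_shared_direction_decreases_distance_opposite_increases(self):
        base_u, base_v = [1, 0, -1, 0], [0, 1, -1, 0]
        d0 = euclidean_distance_matrix(
            [vec(base_u), vec(base_v, dataset="E")]).iloc[0, 1]
        shared = euclidean_distance_matrix(
            [vec(base_u + [1]), vec(base_v + [1], dataset="E")]).iloc[0, 1]
        opposite = euclidean_distance_matrix(
            [vec(base_u + [1]), vec(base_v + [-1], dataset="E")]).iloc[0, 1]
        assert shared == d0 < opposite

    def test_mismatched_dims_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance_matrix([vec([1, 0]), vec([1], dataset="E")])


class TestHeterogeneity:
    SIG = pd.DataFrame(
        [("P1", 10, "c1"), ("P1", 10, "c2"), ("P1", 20, "c1"),
         ("P2", 5, "c3"), ("P3", 7, "c1"), ("P4", 9, "c2")],
        columns=["protein_id", "site", "composition"])

    def test_glycans_per_site(self):
        dist = glycans_per_site(self.SIG)
        # 5 sites, one of which (P1,10) carries two compositions
        assert dist["per_site"][("P1", 10)] == 2
        assert dist["n_multi"] == 1 and dist["n_single"] == 4
        assert dist["fraction_multi"] == pytest.approx(0.2)

    def test_sites_per_protein(self):
        dist = sites_per_protein(self.SIG)
        assert dist["per_protein"]["P1"] == 2
        assert dist["fraction_multi"] == pytest.approx(0.25)

    def test_three_glycans_one_site_count_one(self):
        sig = pd.DataFrame([("P1", 10, c) for c in ("c1", "c2", "c3")],
                           columns=["protein_id", "site", "composition"])
        assert sites_per_protein(sig)["per_protein"]["P1"] == 1

    def test_empty_input(self):
        empty = self.SIG.iloc[:0]
        assert glycans_per_site(empty)["fraction_multi"] == 0.0
        assert sites_per_protein(empty)["per_protein"] == {}

    def test_permutation_invariance(self, rng):
        shuffled = self.SIG.sample(frac=1.0, random_state=3)
        assert glycans_per_site(shuffled) == glycans_per_site(self.SIG)
        assert sites_per_protein(shuffled) == sites_per_protein(self.SIG)


def upset_reference(sets):
    """Brute-force exact-membership enumeration oracle."""
    names = list(sets)
    universe = set().union(*sets.values())
    counts = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            pattern = frozenset(combo)
            count = 0
            for item in universe:
                membership = frozenset(n for n in names if item in sets[n])
                if membership == pattern:
                    count += 1
            counts[pattern] = count
    return counts


class TestIntersectDatasets:
    def test_worked_example(self):
        result = intersect_datasets({"A": {"x", "y"}, "B": {"y", "z"}})
        assert result["patterns"][frozenset({"A"})] == 1
        assert result["patterns"][frozenset({"B"})] == 1
        assert result["patterns"][frozenset({"A", "B"})] == 1
        assert result["totals"] == {"A": 2, "B": 2}

    def test_identical_and_disjoint(self):
        same = intersect_datasets({"A": {1, 2}, "B": {1, 2}})
        assert same["patterns"][frozenset({"A", "B"})] == 2
        assert same["patterns"][frozenset({"A"})] == 0
        disjoint = intersect_datasets({"A": {1}, "B": {2}})
        assert disjoint["patterns"][frozenset({"A", "B"})] == 0

    def test_matches_enumeration_and_sums_to_union(self, rng):
        for _ in range(20):
            n_sets = rng.integers(2, 6)
            sets = {f"S{i}": set(rng.choice(60, size=rng.integers(0, 30)).tolist())
                    for i in range(n_sets)}
            result = intersect_datasets(sets)
            assert result["patterns"] == upset_reference(sets)
            assert sum(result["patterns"].values()) == len(set().union(*sets.values()))

    def test_rejects_single_set(self):
        with pytest.raises(ValueError):
            intersect_datasets({"A": {1}})


class TestOverlapFraction:
    def test_examples(self):
        assert overlap_fraction({1, 2}, {1, 2}) == 100.0
        assert overlap_fraction({1}, {2}) == 0.0
        assert overlap_fraction({1, 2}, {2, 3, 4}) == pytest.approx(25.0)

    def test_denominators(self):
        a, b = {1, 2, 3}, {3, 4}
        assert overlap_fraction(a, b, "min") == pytest.approx(50.0)
        assert overlap_fraction(a, b, "a") == pytest.approx(100 / 3)
        assert overlap_fraction(a, b, "b") == pytest.approx(50.0)
        with pytest.raises(ValueError):
            overlap_fraction(set(), set())


class TestGlycanProteinNetwork:
    SIG = pd.DataFrame(
        [("P1", 10, "c1", "fucose"), ("P2", 5, "c1", "fucose"),
         ("P1", 20, "c2", "sialic_acid")],
        columns=["protein_id", "site", "composition", "glycan_type"])

    def test_edge_and_node_counts(self):
        edges = glycan_protein_network(self.SIG)
        assert len(edges) == 3  # distinct (composition, protein) pairs
        graph = network_graph(edges)
        assert graph.number_of_nodes() == 4  # 2 glycans + 2 proteins
        assert graph.number_of_edges() == 3

    def test_shared_composition_one_glycan_node_two_edges(self):
        edges = glycan_protein_network(self.SIG[self.SIG.composition == "c1"])
        assert len(edges) == 2
        assert edges["composition"].nunique() == 1

    def test_protein_annotated_with_significant_site_count(self):
        edges = glycan_protein_network(self.SIG)
        assert set(edges.loc[edges.protein_id == "P1", "n_sig_sites"]) == {2}

    def test_empty(self):
        assert glycan_protein_network(self.SIG.iloc[:0]).empty
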