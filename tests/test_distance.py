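from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramastats.binning import CommonGrid
from ramastats.density import build_distribution
from ramastats.distance import (
    DistanceMatrix,
    build_topology,
    cityblock,
    distance_matrix,
    find_open_sets,
    ordered_neighbors,
    pair_match_probability,
    replacement_map,
)
from ramastats.synthetic import BasinSpec, ResidueProfile, sample_residue

from conftest import make_records


def labeled_matrix(labels, entries):
    n = len(labels)
    values = np.zeros((n, n))
    for (a, b), d in entries.items():
        i, j = labels.index(a), labels.index(b)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(labels), values)


class TestCityblock:
    def test_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert cityblock(p, p) == 0.0

    def test_disjoint_supports_hit_the_maximum(self):
        p = np.array([1.0, 0.0, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.5, 0.5])
        assert cityblock(p, q) == pytest.approx(2.0)

    def test_hand_sum(self):
        p = np.array([0.5, 0.5, 0.0])
        q = np.array([0.25, 0.25, 0.5])
        assert cityblock(p, q) == pytest.approx(1.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cityblock(np.zeros(3), np.zeros(4))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=12),
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=12),
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=12),
    )
    @settings(derandomize=True, max_examples=60)
    def test_metric_axioms_on_normalized_vectors(self, a, b, c):
        m = max(len(a), len(b), len(c))

        def norm(v):
            x = np.zeros(m)
            x[: len(v)] = v
            s = x.sum()
            return x / s if s > 0 else np.full(m, 1.0 / m)

        p, q, r = norm(a), norm(b), norm(c)
        dpq, dqr, dpr = cityblock(p, q), cityblock(q, r), cityblock(p, r)
        assert dpq >= 0 and dpq <= 2 + 1e-9
        assert dpq == pytest.approx(cityblock(q, p))
        assert dpr <= dpq + dqr + 1e-9
        if np.array_equal(p, q):
            assert dpq == 0.0


class TestDistanceMatrix:
    def test_identical_samples_give_zero_offdiagonal(self):
        grid = CommonGrid(n_bins_per_axis=36)
        pairs = [(-60, -40), (55, 42), (-120, 133)]
        dists = {
            "Ala": build_distribution(make_records("Ala", pairs), grid),
            "Gly": build_distribution(make_records("Gly", pairs), grid),
        }
        m = distance_matrix(dists)
        assert m.d("Ala", "Gly") == 0.0

    def test_pairwise_hand_values(self):
        grid = CommonGrid(n_bins_per_axis=36)
        w = grid.bin_width
        def center(i, j):
            return (-180 + (i + 0.5) * w, -180 + (j + 0.5) * w)
        bins = [center(5, 5), center(18, 18), center(30, 20)]
        # A: [0.5, 0.5, 0] over bins 0/1; B: [0.25, 0.25, 0.5]
        recs_a = make_records("Ala", [bins[0], bins[0], bins[1], bins[1]])
        recs_b = make_records("Gly", [bins[0], bins[1], bins[2], bins[2]])
        dists = {
            "Ala": build_distribution(recs_a, grid),
            "Gly": build_distribution(recs_b, grid),
        }
        m = distance_matrix(dists)
        assert m.d("Ala", "Gly") == pytest.approx(1.0)

    def test_empty_distribution_excluded_with_warning(self):
        grid = CommonGrid(n_bins_per_axis=36)
        dists = {
            "Ala": build_distribution(make_records("Ala", [(0, 0)]), grid),
            "Gly": build_distribution(make_records("Gly", [(1, 1)]), grid),
            "Pro": build_distribution([], grid),
        }
        with pytest.warns(UserWarning, match="empty"):
            m = distance_matrix(dists)
        assert m.labels == ("Ala", "Gly")

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestOrderedNeighbors:
    def test_hand_sort(self):
        m = labeled_matrix(["A", "B", "C"], {("A", "B"): 1, ("A", "C"): 2, ("B", "C"): 3})
        neighbors, ties = ordered_neighbors(m)
        assert neighbors == {"A": ["B", "C"], "B": ["A", "C"], "C": ["A", "B"]}
        assert not any(ties.values())

    def test_tie_breaks_alphabetically_and_flags(self):
        m = labeled_matrix(["A", "B", "C"], {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 2})
        neighbors, ties = ordered_neighbors(m)
        assert neighbors["A"] == ["B", "C"]
        assert ties["A"] and not ties["B"]


def brute_force_open_sets(neighbors):
    """Exhaustive oracle: enumerate every subset of size 2..L-1 and apply the
    membership rule directly."""
    labels = sorted(neighbors)
    found = set()
    for s in range(2, len(labels)):
        for combo in combinations(labels, s):
            S = frozenset(combo)
            if all(set(neighbors[x][: s - 1]) == S - {x} for x in S):
                found.add(S)
    return found


class TestFindOpenSets:
    def test_two_clusters_on_a_line(self):
        m = labeled_matrix(
            ["A", "B", "C", "D"],
            {("A", "B"): 1, ("A", "C"): 10, ("A", "D"): 11,
             ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 1},
        )
        neighbors, _ = ordered_neighbors(m)
        open_sets, _ = find_open_sets(neighbors)
        assert frozenset({"A", "B"}) in open_sets
        assert frozenset({"C", "D"}) in open_sets
        assert open_sets == sorted(brute_force_open_sets(neighbors),
                                   key=lambda s: (len(s), sorted(s)))

    def test_mutual_nearest_neighbors_form_open_pair(self):
        m = labeled_matrix(["A", "B", "C"], {("A", "B"): 1, ("A", "C"): 5, ("B", "C"): 7})
        neighbors, _ = ordered_neighbors(m)
        open_sets, _ = find_open_sets(neighbors)
        assert frozenset({"A", "B"}) in open_sets

    def test_matches_exhaustive_enumeration_on_random_matrices(self, rng):
        for trial in range(30):
            n = int(rng.integers(6, 9))
            labels = [chr(ord("A") + i) for i in range(n)]
            vals = rng.uniform(0.1, 2.0, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0.0)
            m = DistanceMatrix(tuple(labels), vals)
            neighbors, _ = ordered_neighbors(m)
            got, _ = find_open_sets(neighbors)
            assert set(got) == brute_force_open_sets(neighbors)

    def test_planted_boundary_element(self):
        # open 3-set {A, B, C}; satellite D has first 3 neighbors exactly
        # {A, B, C} but A's first 3 neighbors exclude D (E is closer to A),
        # so D is a boundary element, not a member.
        m = labeled_matrix(
            ["A", "B", "C", "D", "E", "F"],
            {("A", "B"): 1.0, ("A", "C"): 1.1, ("B", "C"): 1.2,
             ("A", "D"): 3.0, ("B", "D"): 2.0, ("C", "D"): 2.1,
             ("A", "E"): 2.5, ("B", "E"): 6.0, ("C", "E"): 6.1,
             ("D", "E"): 3.5, ("A", "F"): 9.0, ("B", "F"): 9.1,
             ("C", "F"): 9.2, ("D", "F"): 9.3, ("E", "F"): 8.0},
        )
        neighbors, _ = ordered_neighbors(m)
        open_sets, boundaries = find_open_sets(neighbors)
        S = frozenset({"A", "B", "C"})
        assert S in open_sets
        assert boundaries.get(S) == ["D"]
        # brute force agreement on the sets themselves
        assert set(open_sets) == brute_force_open_sets(neighbors)

    def test_nested_sets_all_reported(self, small_dataset):
        # pairs nested in a larger accepted set are each reported; the
        # minimal filter strips the outer ones
        m = labeled_matrix(
            ["A", "B", "C", "D", "E"],
            {("A", "B"): 1, ("C", "D"): 1.1,
             ("A", "C"): 2, ("A", "D"): 2.2, ("B", "C"): 2.3, ("B", "D"): 2.4,
             ("A", "E"): 8, ("B", "E"): 8, ("C", "E"): 8, ("D", "E"): 8},
        )
        topo = build_topology(m)
        assert frozenset({"A", "B"}) in topo.open_sets
        assert frozenset({"C", "D"}) in topo.open_sets
        assert frozenset({"A", "B", "C", "D"}) in topo.open_sets
        minimal = topo.minimal_open_sets()
        assert frozenset({"A", "B", "C", "D"}) not in minimal


class TestReplacementMap:
    def test_two_labels_forced_reciprocal(self):
        m = labeled_matrix(["A", "B"], {("A", "B"): 1.0})
        repl, reciprocal, _ = replacement_map(m)
        assert repl == {"A": "B", "B": "A"}
        assert reciprocal == {frozenset({"A", "B"})}

    def test_directed_vs_reciprocal(self):
        m = labeled_matrix(
            ["A", "B", "C"], {("A", "B"): 1.0, ("B", "C"): 0.5, ("A", "C"): 2.0}
        )
        repl, reciprocal, _ = replacement_map(m)
        assert repl == {"A": "B", "B": "C", "C": "B"}
        assert reciprocal == {frozenset({"B", "C"})}

    def test_reciprocal_pairs_are_mutual_nearest_neighbors(self, rng):
        for _ in range(20):
            n = 8
            labels = [chr(ord("A") + i) for i in range(n)]
            vals = rng.uniform(0.1, 2.0, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0.0)
            m = DistanceMatrix(tuple(labels), vals)
            repl, reciprocal, _ = replacement_map(m)
            neighbors, _ = ordered_neighbors(m)
            mutual = {
                frozenset((x, y))
                for x in labels
                for y in [neighbors[x][0]]
                if neighbors[y][0] == x
            }
            assert reciprocal == mutual

    def test_zero_distance_duplicates_skipped(self):
        m = labeled_matrix(["A", "B", "C"], {("A", "B"): 0.0, ("A", "C"): 1.0,
                                             ("B", "C"): 2.0})
        repl, _, _ = replacement_map(m)
        assert repl["A"] == "C"


class TestSharedProfileRecovery:
    def test_identical_profiles_become_mutual_nearest_neighbors(self):
        # two residue pairs share mixtures (different seeds); at n = 5000
        # each pair must form an open 2-set
        grid = CommonGrid(n_bins_per_axis=190)
        alpha = (BasinSpec("alpha", (-63.0, -43.0), (12.0, 12.0), weight=0.7),
                 BasinSpec("beta", (-120.0, 130.0), (20.0, 22.0), weight=0.3))
        ppii = (BasinSpec("ppii", (-75.0, 145.0), (14.0, 16.0), weight=0.6),
                BasinSpec("alpha", (-63.0, -43.0), (12.0, 12.0), weight=0.4))
        profiles = {
            "Ala": ResidueProfile("Ala", alpha, 5000, seed=1),
            "Gly": ResidueProfile("Gly", alpha, 5000, seed=2),
            "His": ResidueProfile("His", ppii, 5000, seed=3),
            "Trp": ResidueProfile("Trp", ppii, 5000, seed=4),
        }
        dists = {
            res: build_distribution(sample_residue(p), grid)
            for res, p in profiles.items()
        }
        topo = build_topology(distance_matrix(dists))
        assert frozenset({"Ala", "Gly"}) in topo.reciprocal
        assert frozenset({"His", "Trp"}) in topo.reciprocal
        assert frozenset({"Ala", "Gly"}) in topo.open_sets
        assert frozenset({"His", "Trp"}) in topo.open_sets


class TestPairMatchProbability:
    def test_single_forced_pair(self):
        assert pair_match_probability(1, 1) == Fraction(1)

    def test_two_pairs_one_match(self):
        assert pair_match_probability(2, 1) == Fraction(1, 6)

    def test_six_of_seven_published_value(self):
        p = pair_match_probability(7, 6)
        assert p == Fraction(1, 681_080_400)
        assert float(p) == pytest.approx(1.468e-9, rel=1e-3)

    def test_denominator_factorisation(self):
        assert 6 * 15 * 28 * 45 * 66 * 91 == pair_match_probability(7, 6).denominator

    @pytest.mark.parametrize("n, m", [(0, 0), (3, 4), (5, 0), (-1, 1)])
    def test_invalid_arguments(self, n, m):
        with pytest.raises(ValueError):
            pair_match_probability(n, m)
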