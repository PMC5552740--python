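"""City-block distance topology over the twenty Ramachandran distributions.

The city-block (Manhattan, L1) distance between two binned probability
distributions — the sum of absolute per-bin probability differences — is at
most 2 for normalised distributions and weights the most populated
conformations most heavily. The metric induces a topology on the residue
set: per-residue neighbour lists ordered by increasing distance, *open
subsets* (every member's nearest |S|-1 neighbours are exactly the other
members), boundary elements, and a directed replacement map X -> Y where Y
attains the smallest strictly positive distance to X. Reciprocal
replacements (X <-> Y) are exactly the mutual-nearest-neighbour pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cityblock as _scipy_cityblock

from .density import RamachandranDistribution


def cityblock(p: np.ndarray, q: np.ndarray) -> float:
    """City-block distance between two probability grids on the same grid."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"mismatched grids: {p.shape} vs {q.shape}")
    return float(_scipy_cityblock(p.ravel(), q.ravel()))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative residue-by-residue distance matrix."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def d(self, x: str, y: str) -> float:
        i, j = self.labels.index(x), self.labels.index(y)
        return float(self.values[i, j])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        return cls(tuple(frame.index), frame.to_numpy())


def distance_matrix(
    dists: Mapping[str, RamachandranDistribution]
) -> DistanceMatrix:
    """Full pairwise city-block matrix; row X is the distance set D_X.

    Distances are computed on probability fractions (not percentages or raw
    counts) so the theoretical maximum is 2 and sample-size scale cancels.
    Empty distributions are excluded with a warning and the matrix shrinks.
    """
    import warnings

    usable = {}
    for res in sorted(dists):
        if dists[res].n_obs == 0:
            warnings.warn(f"excluding empty distribution for {res}")
            continue
        usable[res] = dists[res]
    labels = tuple(usable)
    grids = [usable[r].probabilities.ravel() for r in labels]
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError("distributions are not on a common grid")
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        values[i, j] = values[j, i] = np.abs(grids[i] - grids[j]).sum()
    return DistanceMatrix(labels, values)


@dataclass
class NeighborTopology:
    """Ordered neighbour lists, open subsets, boundaries and replacements."""

    labels: tuple[str, ...]
    ordered_neighbors: dict[str, list[str]]
    ties: dict[str, bool]
    open_sets: list[frozenset[str]] = field(default_factory=list)
    boundary_elements: dict[frozenset[str], list[str]] = field(default_factory=dict)
    replacements: dict[str, str] = field(default_factory=dict)
    reciprocal: set[frozenset[str]] = field(default_factory=set)

    def neighbors_frame(self) -> pd.DataFrame:
        """Ranked-neighbour table, one row per residue."""
        ncols = len(self.labels) - 1
        return pd.DataFrame(
            {res: self.ordered_neighbors[res] for res in self.labels},
            index=[f"nn{i+1}" for i in range(ncols)],
        ).T

    def reciprocal_pairs(self) -> set[frozenset[str]]:
        return set(self.reciprocal)

    def minimal_open_sets(self) -> list[frozenset[str]]:
        """Open sets that contain no smaller accepted open set."""
        return [
            s for s in self.open_sets
            if not any(t < s for t in self.open_sets if t != s)
        ]


def ordered_neighbors(
    matrix: DistanceMatrix,
) -> tuple[dict[str, list[str]], dict[str, bool]]:
    """Per-residue neighbour lists sorted by increasing distance.

    Exact distance ties are broken alphabetically by residue code and the
    residue is flagged in the returned tie map.
    """
    neighbors: dict[str, list[str]] = {}
    ties: dict[str, bool] = {}
    for i, x in enumerate(matrix.labels):
        pairs = [
            (matrix.values[i, j], y)
            for j, y in enumerate(matrix.labels)
            if j != i
        ]
        pairs.sort(key=lambda t: (t[0], t[1]))
        dvals = [d for d, _ in pairs]
        ties[x] = len(dvals) != len(set(dvals))
        neighbors[x] = [y for _, y in pairs]
    return neighbors, ties


def find_open_sets(
    neighbors: Mapping[str, Sequence[str]],
) -> tuple[list[frozenset[str]], dict[frozenset[str], list[str]]]:
    """Open subsets of the neighbour topology, with boundary elements.

    A candidate S = {X} + (first s-1 neighbours of X) of size s is accepted
    iff every member's first s-1 neighbours lie inside S — i.e. each
    member's nearest s-1 neighbours are exactly the other members. Sets of
    every size from 2 to |labels|-1 are reported (nested accepted sets are
    all kept; see :meth:`NeighborTopology.minimal_open_sets` for the
    filter).

    A boundary element of an accepted S is an outside residue Z whose first
    |S| neighbours are exactly S but where some member of S lacks Z among
    its own first |S| neighbours, so S + {Z} is not itself open.
    """
    labels = sorted(neighbors)
    L = len(labels)
    accepted: set[frozenset[str]] = set()
    for s in range(2, L):
        for x in labels:
            cand = frozenset([x, *neighbors[x][: s - 1]])
            if len(cand) != s:
                continue
            if all(set(neighbors[y][: s - 1]) <= cand for y in cand):
                accepted.add(cand)
    open_sets = sorted(accepted, key=lambda s: (len(s), sorted(s)))
    boundaries: dict[frozenset[str], list[str]] = {}
    for S in open_sets:
        k = len(S)
        bnd = []
        for z in labels:
            if z in S:
                continue
            if set(neighbors[z][:k]) == set(S) and any(
                z not in neighbors[y][:k] for y in S
            ):
                bnd.append(z)
        if bnd:
            boundaries[S] = sorted(bnd)
    return open_sets, boundaries


def replacement_map(
    matrix: DistanceMatrix,
) -> tuple[dict[str, str], set[frozenset[str]], dict[str, bool]]:
    """Directed replacements X -> argmin over strictly positive distances.

    Returns (replacements, reciprocal pairs, tie flags). Zero off-diagonal
    distances (duplicate distributions) are skipped by the positivity
    requirement; distance ties are broken alphabetically and flagged.
    """
    replacements: dict[str, str] = {}
    ties: dict[str, bool] = {}
    for i, x in enumerate(matrix.labels):
        candidates = [
            (matrix.values[i, j], y)
            for j, y in enumerate(matrix.labels)
            if j != i and matrix.values[i, j] > 0
        ]
        if not candidates:
            continue
        dmin = min(d for d, _ in candidates)
        best = sorted(y for d, y in candidates if d == dmin)
        ties[x] = len(best) > 1
        replacements[x] = best[0]
    reciprocal = {
        frozenset([x, y])
        for x, y in replacements.items()
        if replacements.get(y) == x
    }
    return replacements, reciprocal, ties


def build_topology(matrix: DistanceMatrix) -> NeighborTopology:
    """Assemble the full neighbour topology from a distance matrix."""
    neighbors, ties = ordered_neighbors(matrix)
    open_sets, boundaries = find_open_sets(neighbors)
    replacements, reciprocal, _ = replacement_map(matrix)
    return NeighborTopology(
        labels=matrix.labels,
        ordered_neighbors=neighbors,
        ties=ties,
        open_sets=open_sets,
        boundary_elements=boundaries,
        replacements=replacements,
        reciprocal=reciprocal,
    )


def pair_match_probability(total_pairs: int, matched_pairs: int) -> Fraction:
    """Probability of sequentially matching ``matched_pairs`` disjoint pairs
    out of ``total_pairs`` pairs (2*total_pairs elements) at random.

    The j-th success draws one element of a remaining pair (probability
    2/(2n - 2j)) and then its partner (1/(2n - 2j - 1)), giving

        prod_{j=0}^{m-1} 2 / ((2n - 2j) * (2n - 2j - 1))

    as an exact rational. For (n, m) = (7, 6) the product telescopes to
    1/681,080,400.
    """
    n, m = int(total_pairs), int(matched_pairs)
    if m < 1 or n < 1 or m > n:
        raise ValueError("need 1 <= matched_pairs <= total_pairs")
    prob = Fraction(1)
    for j in range(m):
        prob *= Fraction(2, (2 * n - 2 * j) * (2 * n - 2 * j - 1))
    return prob
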