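"""Model/Results interface over the full analysis.

:class:`RamachandranModel` is built from dihedral observations (a record
list, a DataFrame, or a TSV); ``fit()`` optimises per-residue bin widths,
forms the common grid, estimates the per-residue Ramachandran
distributions, and returns a :class:`RamachandranResults` carrying the
estimates (Delta_X, N_X, P_X^max, W_X, I_X), the city-block distance
topology and the correlation analyses, with a ``summary()`` table.

    >>> from ramastats import synthetic
    >>> from ramastats.model import RamachandranModel
    >>> records, _ = synthetic.generate_dataset(synthetic.default_profiles(500))
    >>> res = RamachandranModel(records).fit(k_range=range(10, 101, 5))
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .binning import BinSweepResult, CommonGrid, common_grid, optimize_bin_width
from .density import RamachandranDistribution, summarize_all
from .dihedral_io import DihedralRecord, read_dihedral_table
from .distance import DistanceMatrix, NeighborTopology, build_topology, distance_matrix
from .inertia import (
    HelixPartition,
    SubstitutionMatrix,
    SurveyResult,
    build_table,
    correlation_survey,
    helix_former_partition,
    pearson,
)


class RamachandranModel:
    """Secondary-structure statistics model for a set of dihedral records.

    Parameters
    ----------
    records
        Dihedral observations; each carries a canonical residue identity
        and wrapped (phi, psi) angles in degrees.
    constants
        Per-residue physical constants (columns ``mass``, ``b_steps``);
        defaults to the built-in published values.
    """

    def __init__(
        self,
        records: Sequence[DihedralRecord],
        constants: pd.DataFrame | None = None,
    ) -> None:
        self.records = list(records)
        if not self.records:
            raise ValueError("no records")
        self.constants = constants if constants is not None else reference.constants()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "RamachandranModel":
        """Build from a DataFrame with columns residue, phi, psi."""
        from .dihedral_io import wrap_angle
        from .residues import canonicalize

        records = [
            DihedralRecord(
                canonicalize(str(row["residue"])),
                wrap_angle(float(row["phi"])),
                wrap_angle(float(row["psi"])),
            )
            for _, row in frame.iterrows()
        ]
        return cls(records, **kwargs)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "RamachandranModel":
        records, _ = read_dihedral_table(path)
        return cls(records, **kwargs)

    def fit(
        self,
        k_range: Iterable[int] = range(10, 401),
        *,
        grid: CommonGrid | None = None,
    ) -> "RamachandranResults":
        """Run the binning-density-distance-inertia chain.

        With ``grid`` given, the per-residue bin-width sweeps are skipped
        and densities are estimated directly on that grid.
        """
        ks = list(k_range)
        by_residue: dict[str, list[DihedralRecord]] = {}
        for rec in self.records:
            by_residue.setdefault(rec.residue, []).append(rec)
        sweeps: dict[str, BinSweepResult] = {}
        if grid is None:
            for res in sorted(by_residue):
                sweeps[res] = optimize_bin_width(by_residue[res], ks, residue=res)
            grid = common_grid(
                (s.delta_min, s.n_obs) for s in sweeps.values()
            )
        dists, summary = summarize_all(self.records, grid)
        table = build_table(summary, self.constants, require_all=False)
        if sweeps:
            table.insert(2, "delta_min", pd.Series({r: s.delta_min for r, s in sweeps.items()}))
        matrix = distance_matrix(dists)
        topology = build_topology(matrix)
        return RamachandranResults(
            model=self,
            grid=grid,
            sweeps=sweeps,
            distributions=dists,
            table=table,
            matrix=matrix,
            topology=topology,
        )


@dataclass
class RamachandranResults:
    """Fitted per-residue distributions, topology and derived statistics."""

    model: RamachandranModel
    grid: CommonGrid
    sweeps: dict[str, BinSweepResult]
    distributions: dict[str, RamachandranDistribution]
    table: pd.DataFrame
    matrix: DistanceMatrix
    topology: NeighborTopology

    @property
    def inertia(self) -> pd.Series:
        """The mutational-inertia scale I_X."""
        return self.table["inertia"]

    def helix_partition(self, threshold: float = 0.200) -> HelixPartition:
        return helix_former_partition(self.table, threshold)

    def mass_vs_bsteps(self, exclude: Iterable[str] | None = None) -> float:
        return pearson(self.table["mass"], self.table["b_steps"], exclude=exclude)

    def mutability_survey(
        self, matrices: Sequence[SubstitutionMatrix]
    ) -> SurveyResult:
        return correlation_survey(self.inertia, matrices)

    def summary(self) -> str:
        """Human-readable fit summary in the style of a regression report."""
        lines = [
            "Ramachandran secondary-structure statistics",
            "=" * 62,
            f"observations: {sum(d.n_obs for d in self.distributions.values())}"
            f"   residue types: {len(self.distributions)}",
            f"common grid: {self.grid.n_bins_per_axis} x {self.grid.n_bins_per_axis} bins"
            f" ({self.grid.bin_width:.3f} deg/bin"
            + (
                f", weighted-mean optimal width {self.grid.delta_bar:.3f} deg)"
                if self.grid.delta_bar is not None
                else ")"
            ),
            "",
            self.table.round(
                {"mass": 3, "delta_min": 3, "p_max_percent": 3, "w": 3, "inertia": 3}
            ).to_string(),
            "",
            f"replacements: "
            + ", ".join(
                f"{x}<->{y}" if frozenset((x, y)) in self.topology.reciprocal
                else f"{x}->{y}"
                for x, y in sorted(self.topology.replacements.items())
            ),
        ]
        if self.topology.open_sets:
            lines.append(
                "open sets: "
                + "; ".join("{" + ", ".join(sorted(s)) + "}" for s in self.topology.open_sets)
            )
        return "\n".join(lines)

    def plot_distance_matrix(self, ax=None):
        from .plotting import plot_distance_matrix

        return plot_distance_matrix(self.matrix, self.topology, ax=ax)

    def plot_density(self, residue: str, ax=None):
        from .plotting import plot_density

        return plot_density(self.distributions[residue], ax=ax)
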