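"""Per-residue Ramachandran probability distributions on a common grid.

A Ramachandran probability distribution P_X(phi, psi) is the joint
histogram of a residue's backbone dihedral observations, normalised to
probabilities. Its peak P_X^max — the mass of the most populated bin — is
the probability of the residue's most frequent backbone conformation and
is the structural-persistence statistic used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import CommonGrid, bin_counts
from .dihedral_io import DihedralRecord


@dataclass
class RamachandranDistribution:
    """Binned joint probability over the torus for one residue."""

    residue: str
    grid: CommonGrid
    counts: np.ndarray                 # (k, k) int
    n_obs: int
    modal_tie: bool = False

    def __post_init__(self) -> None:
        k = self.grid.n_bins_per_axis
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != grid ({k}, {k})")
        if int(self.counts.sum()) != self.n_obs:
            raise ValueError("counts do not sum to n_obs")

    @property
    def probabilities(self) -> np.ndarray:
        """Per-bin probability fractions (undefined for an empty distribution)."""
        if self.n_obs == 0:
            raise ValueError(f"empty distribution for {self.residue}")
        return self.counts / float(self.n_obs)

    @property
    def p_max(self) -> float:
        """Largest bin probability, as a fraction."""
        return float(self.probabilities.max())

    @property
    def modal_bin(self) -> tuple[int, int]:
        """(phi index, psi index) of the peak; ties take the smallest (i, j)."""
        flat = int(np.argmax(self.counts))   # C order == lexicographic (i, j)
        k = self.grid.n_bins_per_axis
        return (flat // k, flat % k)

    @property
    def modal_bin_center(self) -> tuple[float, float]:
        i, j = self.modal_bin
        w = self.grid.bin_width
        return (-180.0 + (i + 0.5) * w, -180.0 + (j + 0.5) * w)


def build_distribution(
    records: Sequence[DihedralRecord], grid: CommonGrid
) -> RamachandranDistribution:
    """Histogram one residue's records on the common grid.

    Bin (i, j) covers [-180 + i*w, -180 + (i+1)*w) on each axis. An empty
    record list yields a distribution with n_obs = 0 whose probabilities are
    flagged as undefined; mixed residue identities are an error.
    """
    records = list(records)
    residues = {r.residue for r in records}
    if len(residues) > 1:
        raise ValueError(f"mixed residues in one distribution: {sorted(residues)}")
    residue = records[0].residue if records else "?"
    k = grid.n_bins_per_axis
    if not records:
        return RamachandranDistribution(residue, grid, np.zeros((k, k), dtype=np.int64), 0)
    counts = bin_counts(records, k)
    dist = RamachandranDistribution(residue, grid, counts, len(records))
    dist.modal_tie = int((counts == counts.max()).sum()) > 1
    return dist


def p_max_percent(dist: RamachandranDistribution) -> float:
    """The distribution peak as a percentage (the conventional reporting unit)."""
    if dist.n_obs == 0:
        raise ValueError(f"empty distribution for {dist.residue}")
    return 100.0 * dist.p_max


def summarize_all(
    records: Sequence[DihedralRecord], grid: CommonGrid
) -> tuple[dict[str, RamachandranDistribution], pd.DataFrame]:
    """One distribution per residue present, plus a summary table.

    The summary has one row per residue: N_X, p_max (fraction and percent)
    and the modal-bin center, sorted alphabetically by residue.
    """
    records = list(records)
    if not records:
        raise ValueError("empty dataset")
    by_residue: dict[str, list[DihedralRecord]] = {}
    for rec in records:
        by_residue.setdefault(rec.residue, []).append(rec)
    dists = {
        res: build_distribution(recs, grid) for res, recs in sorted(by_residue.items())
    }
    rows = []
    for res, dist in dists.items():
        phi_c, psi_c = dist.modal_bin_center
        rows.append({
            "residue": res,
            "n_obs": dist.n_obs,
            "p_max_fraction": dist.p_max,
            "p_max_percent": p_max_percent(dist),
            "modal_phi_center": phi_c,
            "modal_psi_center": psi_c,
        })
    return dists, pd.DataFrame(rows).set_index("residue")


def dump_distribution(dist: RamachandranDistribution, path) -> None:
    """Write the count grid as whitespace-separated integers (round-trippable)."""
    header = f"residue={dist.residue} k={dist.grid.n_bins_per_axis} n_obs={dist.n_obs}"
    np.savetxt(path, dist.counts, fmt="%d", header=header)


def load_distribution(path) -> RamachandranDistribution:
    """Read a grid written by :func:`dump_distribution`."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(kv.split("=") for kv in header.split())
    counts = np.loadtxt(path, dtype=np.int64)
    grid = CommonGrid(n_bins_per_axis=int(meta["k"]))
    return RamachandranDistribution(meta["residue"], grid, counts, int(meta["n_obs"]))
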