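"""Synthetic Ramachandran-sample generator.

Draws per-residue (phi, psi) observations from mixtures of wrapped
bivariate Gaussian basins placed at the canonical secondary-structure
regions of the Ramachandran map (alpha-helix, beta, polyproline-II and
left-handed alpha). Every downstream stage — bin-width optimisation,
density estimation, the city-block distance topology and the inertia
statistics — is testable against the known basin weights and the analytic
modal-bin mass of the mixture, without access to a curated structure
database.

Wrapping a plane Gaussian onto the torus (rather than sampling a true
wrapped/von Mises density) is adequate because the default spreads
(10-25 degrees) are far below the 360-degree period; the approximation is
a documented limitation, not an accident.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .dihedral_io import DihedralRecord, wrap_angles
from .residues import CANONICAL, canonicalize

#: Canonical basin centers (degrees) on the Ramachandran map.
BASIN_CENTERS: dict[str, tuple[float, float]] = {
    "alpha": (-63.0, -43.0),
    "beta": (-120.0, 130.0),
    "ppii": (-75.0, 145.0),
    "left_alpha": (60.0, 45.0),
}


@dataclass(frozen=True)
class BasinSpec:
    """One wrapped bivariate Gaussian basin of a residue's mixture."""

    name: str
    center: tuple[float, float]
    spread: tuple[float, float] = (15.0, 15.0)
    correlation: float = 0.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.spread[0] <= 0 or self.spread[1] <= 0:
            raise ValueError("spreads must be positive")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if not (-180.0 <= self.center[0] < 180.0 and -180.0 <= self.center[1] < 180.0):
            raise ValueError("basin centers must lie in [-180, 180)")


@dataclass(frozen=True)
class ResidueProfile:
    """Mixture specification and sample size for one residue."""

    residue: str
    basins: tuple[BasinSpec, ...]
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.basins:
            raise ValueError("at least one basin required")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        object.__setattr__(self, "residue", canonicalize(self.residue))

    @property
    def weights(self) -> np.ndarray:
        """Normalised basin weights."""
        w = np.array([b.weight for b in self.basins], dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("all basin weights are zero")
        return w / total


def sample_residue(profile: ResidueProfile, *, return_assignments: bool = False):
    """Draw ``profile.n_samples`` dihedral records from the basin mixture.

    Each draw picks a basin with probability equal to its normalised weight,
    then draws (phi, psi) from that basin's bivariate Gaussian and wraps both
    angles onto [-180, 180). Deterministic given ``profile.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(profile.seed))
    w = profile.weights
    n = profile.n_samples
    assignments = rng.choice(len(w), size=n, p=w)
    phi = np.empty(n)
    psi = np.empty(n)
    for k, basin in enumerate(profile.basins):
        mask = assignments == k
        m = int(mask.sum())
        if m == 0:
            continue
        sx, sy = basin.spread
        rho = basin.correlation
        cov = np.array([[sx * sx, rho * sx * sy], [rho * sx * sy, sy * sy]])
        draws = rng.multivariate_normal(basin.center, cov, size=m, method="cholesky")
        phi[mask] = draws[:, 0]
        psi[mask] = draws[:, 1]
    phi = wrap_angles(phi)
    psi = wrap_angles(psi)
    records = [
        DihedralRecord(profile.residue, float(phi[i]), float(psi[i]), source_id="synthetic")
        for i in range(n)
    ]
    if return_assignments:
        return records, assignments
    return records


# Per-residue basin weights (alpha, beta, ppii, left_alpha). Constructed to
# satisfy the qualitative constraints of observed distributions: Gly has a
# left-handed-alpha peak comparable to its alpha peak; Pro populates only the
# alpha and PPII basins with PPII dominant; the conformationally restricted
# set {Ile, Pro, Thr, Val} carries no weight at phi > 0; everything else is
# alpha-dominant with Ala the strongest helix former.
_DEFAULT_WEIGHTS: dict[str, dict[str, float]] = {
    "Ala": {"alpha": 0.70, "beta": 0.10, "ppii": 0.15, "left_alpha": 0.05},
    "Arg": {"alpha": 0.55, "beta": 0.20, "ppii": 0.20, "left_alpha": 0.05},
    "Asn": {"alpha": 0.45, "beta": 0.20, "ppii": 0.20, "left_alpha": 0.15},
    "Asp": {"alpha": 0.47, "beta": 0.19, "ppii": 0.20, "left_alpha": 0.14},
    "Cys": {"alpha": 0.45, "beta": 0.30, "ppii": 0.20, "left_alpha": 0.05},
    "Gln": {"alpha": 0.58, "beta": 0.18, "ppii": 0.19, "left_alpha": 0.05},
    "Glu": {"alpha": 0.60, "beta": 0.16, "ppii": 0.19, "left_alpha": 0.05},
    "Gly": {"alpha": 0.35, "beta": 0.15, "ppii": 0.20, "left_alpha": 0.30},
    "His": {"alpha": 0.48, "beta": 0.25, "ppii": 0.20, "left_alpha": 0.07},
    "Ile": {"alpha": 0.55, "beta": 0.30, "ppii": 0.15, "left_alpha": 0.0},
    "Leu": {"alpha": 0.57, "beta": 0.24, "ppii": 0.16, "left_alpha": 0.03},
    "Lys": {"alpha": 0.56, "beta": 0.19, "ppii": 0.20, "left_alpha": 0.05},
    "Met": {"alpha": 0.56, "beta": 0.22, "ppii": 0.17, "left_alpha": 0.05},
    "Phe": {"alpha": 0.48, "beta": 0.30, "ppii": 0.18, "left_alpha": 0.04},
    "Pro": {"alpha": 0.42, "beta": 0.0, "ppii": 0.58, "left_alpha": 0.0},
    "Ser": {"alpha": 0.46, "beta": 0.23, "ppii": 0.23, "left_alpha": 0.08},
    "Thr": {"alpha": 0.50, "beta": 0.30, "ppii": 0.20, "left_alpha": 0.0},
    "Trp": {"alpha": 0.50, "beta": 0.28, "ppii": 0.18, "left_alpha": 0.04},
    "Tyr": {"alpha": 0.47, "beta": 0.31, "ppii": 0.18, "left_alpha": 0.04},
    "Val": {"alpha": 0.52, "beta": 0.33, "ppii": 0.15, "left_alpha": 0.0},
}

_DEFAULT_SPREADS: dict[str, tuple[float, float]] = {
    "alpha": (12.0, 12.0),
    "beta": (20.0, 22.0),
    "ppii": (14.0, 16.0),
    "left_alpha": (13.0, 13.0),
}


def default_profiles(
    scale: int = 1000, *, master_seed: int = 0
) -> dict[str, ResidueProfile]:
    """Default per-residue mixture profiles at ``scale`` samples per residue.

    Per-residue random streams are derived deterministically from
    ``master_seed`` via ``SeedSequence(master_seed, spawn_key=(index,))`` with
    ``index`` the residue's position in alphabetical canonical order, so
    regenerating a single residue is stable.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    profiles: dict[str, ResidueProfile] = {}
    for idx, residue in enumerate(CANONICAL):
        basins = tuple(
            BasinSpec(
                name=bn,
                center=BASIN_CENTERS[bn],
                spread=_DEFAULT_SPREADS[bn],
                weight=wt,
            )
            for bn, wt in _DEFAULT_WEIGHTS[residue].items()
            if wt > 0
        )
        seed = int(
            np.random.SeedSequence(master_seed, spawn_key=(idx,)).generate_state(1)[0]
            % (2**31)
        )
        profiles[residue] = ResidueProfile(residue, basins, n_samples=scale, seed=seed)
    return profiles


@dataclass
class GroundTruth:
    """Sidecar truth for a generated dataset: weights and modal-bin mass."""

    master_seed: int
    per_residue: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"master_seed": self.master_seed, "per_residue": self.per_residue},
            indent=1, sort_keys=True,
        ))


def generate_dataset(
    profiles: Mapping[str, ResidueProfile],
    *,
    master_seed: int = 0,
    grid_bins: int = 190,
    compute_modal_mass: bool = True,
) -> tuple[list[DihedralRecord], GroundTruth]:
    """Concatenated samples for all residues plus a ground-truth record.

    The ground truth stores, per residue, the normalised basin weights and
    (optionally) the analytic modal-bin mass of the mixture on a
    ``grid_bins`` x ``grid_bins`` torus grid, so recovery tests never
    re-derive the truth from the samples themselves.
    """
    records: list[DihedralRecord] = []
    truth = GroundTruth(master_seed=master_seed)
    for residue in sorted(profiles):
        profile = profiles[residue]
        records.extend(sample_residue(profile))
        entry = {
            "n_samples": profile.n_samples,
            "seed": profile.seed,
            "weights": {b.name: float(w) for b, w in zip(profile.basins, profile.weights)},
        }
        if compute_modal_mass:
            mass, modal_bin = analytic_modal_bin_mass(profile, grid_bins)
            entry["modal_bin_mass"] = mass
            entry["modal_bin"] = list(modal_bin)
        truth.per_residue[residue] = entry
    return records, truth


def _gauss_cdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return 0.5 * (1.0 + erf((x - mu) / (sigma * np.sqrt(2.0))))


def analytic_bin_masses(
    profile: ResidueProfile, n_bins: int = 190, n_wraps: int = 2
) -> np.ndarray:
    """Exact mixture probability mass of every bin of an n_bins^2 torus grid.

    Basin components are axis-aligned in the default profiles (zero
    correlation), so each bin's mass factorises into products of 1D Gaussian
    CDF differences, summed over ``n_wraps`` periodic images per side.
    Profiles with correlated basins are rejected.
    """
    if any(b.correlation != 0.0 for b in profile.basins):
        raise NotImplementedError("analytic bin mass requires axis-aligned basins")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    total = np.zeros((n_bins, n_bins))
    for basin, w in zip(profile.basins, profile.weights):
        masses = []
        for axis in range(2):
            mu = basin.center[axis]
            sigma = basin.spread[axis]
            m = np.zeros(n_bins)
            for k in range(-n_wraps, n_wraps + 1):
                lo = _gauss_cdf(edges[:-1] + 360.0 * k, mu, sigma)
                hi = _gauss_cdf(edges[1:] + 360.0 * k, mu, sigma)
                m += hi - lo
            masses.append(m)
        total += w * np.outer(masses[0], masses[1])
    return total


def analytic_modal_bin_mass(
    profile: ResidueProfile, n_bins: int = 190, n_wraps: int = 2
) -> tuple[float, tuple[int, int]]:
    """Largest analytic bin mass of the mixture and its (i, j) bin index."""
    total = analytic_bin_masses(profile, n_bins, n_wraps)
    flat = int(np.argmax(total))
    modal = (flat // n_bins, flat % n_bins)
    return float(total[modal]), modal


def profiles_from_config(config: Mapping | str | Path) -> dict[str, ResidueProfile]:
    """Build profiles from a YAML/JSON config mapping or file path.

    Schema: ``{residue: {seed: int, n_samples: int, basins: [{name, center,
    spread, correlation, weight}, ...]}}``. Omitted basin fields fall back to
    the canonical center/spread for that basin name.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    profiles = {}
    for residue, spec in config.items():
        basins = tuple(
            BasinSpec(
                name=b["name"],
                center=tuple(b.get("center", BASIN_CENTERS[b["name"]])),
                spread=tuple(b.get("spread", _DEFAULT_SPREADS.get(b["name"], (15.0, 15.0)))),
                correlation=float(b.get("correlation", 0.0)),
                weight=float(b.get("weight", 1.0)),
            )
            for b in spec["basins"]
        )
        profiles[canonicalize(residue)] = ResidueProfile(
            residue,
            basins,
            n_samples=int(spec.get("n_samples", 1000)),
            seed=int(spec.get("seed", 0)),
        )
    return profiles


def profile_to_dict(profile: ResidueProfile) -> dict:
    """JSON/YAML-serialisable form of a profile (round-trips via config)."""
    return {
        "n_samples": profile.n_samples,
        "seed": profile.seed,
        "basins": [asdict(b) for b in profile.basins],
    }
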