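"""Reading, validating and computing backbone dihedral observations.

The canonical angle convention throughout the package is degrees on the
half-open interval [-180, 180); +180 wraps to -180 so that binning at the
seam of the torus is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .residues import UnknownResidueError, canonicalize


@dataclass(frozen=True)
class DihedralRecord:
    """One observed backbone conformation: residue identity plus (phi, psi)."""

    residue: str
    phi: float
    psi: float
    source_id: str | None = None


@dataclass
class ParseReport:
    """Line accounting for a table parse: read / kept / rejected."""

    lines_read: int = 0
    lines_kept: int = 0
    lines_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, lineno: int, reason: str) -> None:
        self.lines_rejected += 1
        self.rejections.append((lineno, reason))


def wrap_angle(x: float) -> float:
    """Wrap an angle in degrees onto [-180, 180).

    The result is congruent to ``x`` modulo 360 and the map is idempotent;
    +180 maps to -180 (lower edge of the half-open interval).
    """
    if not math.isfinite(x):
        raise ValueError(f"non-finite angle: {x!r}")
    return (x + 180.0) % 360.0 - 180.0


def wrap_angles(x: np.ndarray) -> np.ndarray:
    """Vectorised :func:`wrap_angle`."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite angle in array")
    return (x + 180.0) % 360.0 - 180.0


def read_dihedral_table(
    path: str | Path,
    *,
    strict: bool = False,
) -> tuple[list[DihedralRecord], ParseReport]:
    """Read a dihedral TSV (columns: residue, phi, psi, optional source_id).

    Whitespace- or tab-separated; lines starting with '#' and blank lines are
    skipped. Angles are wrapped onto [-180, 180). Malformed lines are
    rejected and recorded in the report (``strict=True`` raises instead).
    A single leading header line of the form ``residue phi psi ...`` is
    tolerated and skipped.
    """
    path = Path(path)
    records: list[DihedralRecord] = []
    report = ParseReport()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            report.lines_read += 1
            fields = line.split()
            if lineno == 1 and fields[0].lower() in ("residue", "res", "aa"):
                report.lines_read -= 1
                continue
            if len(fields) < 3:
                _reject(report, lineno, f"expected >=3 fields, got {len(fields)}", strict)
                continue
            try:
                residue = canonicalize(fields[0])
            except UnknownResidueError as exc:
                _reject(report, lineno, str(exc), strict)
                continue
            try:
                phi = wrap_angle(float(fields[1]))
                psi = wrap_angle(float(fields[2]))
            except ValueError as exc:
                _reject(report, lineno, f"bad angle: {exc}", strict)
                continue
            source_id = fields[3] if len(fields) > 3 else None
            records.append(DihedralRecord(residue, phi, psi, source_id))
            report.lines_kept += 1
    return records, report


def _reject(report: ParseReport, lineno: int, reason: str, strict: bool) -> None:
    if strict:
        raise ValueError(f"line {lineno}: {reason}")
    report.reject(lineno, reason)


def write_dihedral_table(
    records: Iterable[DihedralRecord],
    path: str | Path,
    *,
    precision: int = 6,
) -> None:
    """Write records as the package's dihedral TSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# residue\tphi\tpsi\tsource_id\n")
        for rec in records:
            tail = f"\t{rec.source_id}" if rec.source_id is not None else ""
            fh.write(f"{rec.residue}\t{rec.phi:.{precision}f}\t{rec.psi:.{precision}f}{tail}\n")


def dihedral_angle(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed dihedral (degrees, IUPAC right-hand convention) of four points.

    Zero for the eclipsed (syn-periplanar) arrangement, -180 (wrapped) for
    anti. Raises ``ValueError`` when three consecutive atoms are collinear,
    which leaves the torsion undefined.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1)
    if b1n == 0.0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: collinear atoms in dihedral quadruple")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / b1n))
    return wrap_angle(math.degrees(math.atan2(y, x)))


@dataclass
class BackboneChain:
    """Ordered backbone of one chain: per-residue N, CA, C coordinates."""

    residues: Sequence[str]          # canonical residue names
    n: np.ndarray                    # (L, 3)
    ca: np.ndarray                   # (L, 3)
    c: np.ndarray                    # (L, 3)

    def __post_init__(self) -> None:
        L = len(self.residues)
        for name in ("n", "ca", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L, 3):
                raise ValueError(f"{name} coordinates must have shape ({L}, 3)")
            setattr(self, name, arr)


def compute_backbone_dihedrals(
    chain: BackboneChain,
) -> tuple[list[DihedralRecord], ParseReport]:
    """Compute (phi, psi) for every interior residue of a backbone chain.

    phi_i is the torsion C(i-1)-N(i)-CA(i)-C(i); psi_i is
    N(i)-CA(i)-C(i)-N(i+1). Terminal residues, for which one of the two
    angles is undefined, are skipped, as are residues with degenerate
    (collinear) geometry; skips are recorded in the report.
    """
    L = len(chain.residues)
    if L < 3:
        raise ValueError("need at least 3 consecutive residues")
    records: list[DihedralRecord] = []
    report = ParseReport()
    for i in range(1, L - 1):
        report.lines_read += 1
        try:
            phi = dihedral_angle(chain.c[i - 1], chain.n[i], chain.ca[i], chain.c[i])
            psi = dihedral_angle(chain.n[i], chain.ca[i], chain.c[i], chain.n[i + 1])
        except ValueError as exc:
            report.reject(i, str(exc))
            continue
        records.append(DihedralRecord(chain.residues[i], phi, psi, source_id=f"res{i}"))
        report.lines_kept += 1
    return records, report


def read_backbone_pdb(path: str | Path) -> BackboneChain:
    """Extract one chain's N/CA/C backbone from a PDB file (ATOM records).

    Uses the first model and the first chain; for altlocs the first
    occurrence is taken. Residues lacking any of N/CA/C or carrying a
    non-canonical name are dropped.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    chain_id = atoms.chain_id[0]
    atoms = atoms[atoms.chain_id == chain_id]
    residues: list[str] = []
    coords: dict[str, list[np.ndarray]] = {"N": [], "CA": [], "C": []}
    for res_id in np.unique(atoms.res_id):
        sub = atoms[atoms.res_id == res_id]
        try:
            name = canonicalize(str(sub.res_name[0]))
        except UnknownResidueError:
            continue
        picks = {}
        for atom_name in ("N", "CA", "C"):
            hit = sub[sub.atom_name == atom_name]
            if len(hit) == 0:
                break
            picks[atom_name] = hit.coord[0]
        if len(picks) < 3:
            continue
        residues.append(name)
        for atom_name in ("N", "CA", "C"):
            coords[atom_name].append(picks[atom_name])
    return BackboneChain(
        residues,
        np.array(coords["N"]),
        np.array(coords["CA"]),
        np.array(coords["C"]),
    )
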