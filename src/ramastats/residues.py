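"""Canonical amino-acid identities and code conversion.

Only the twenty canonical residues are recognised; modified residues
(MSE, SEP, ...) are rejected at parse time rather than remapped.
"""

from __future__ import annotations

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Canonical storage form: three-letter, title case (Ala, Arg, ...).
CANONICAL: tuple[str, ...] = tuple(sorted(c.capitalize() for c in THREE_TO_ONE))


class UnknownResidueError(ValueError):
    """Raised for residue codes outside the twenty canonical identities."""


def canonicalize(code: str) -> str:
    """Normalise a 1- or 3-letter residue code to canonical form (e.g. 'Ala').

    Case-insensitive. Raises :class:`UnknownResidueError` for anything that
    is not one of the twenty canonical residues.
    """
    s = code.strip()
    if len(s) == 3 and s.upper() in THREE_TO_ONE:
        return s.capitalize()
    if len(s) == 1 and s.upper() in ONE_TO_THREE:
        return ONE_TO_THREE[s.upper()].capitalize()
    raise UnknownResidueError(f"unknown residue code: {code!r}")


def one_letter(canonical: str) -> str:
    """One-letter code for a canonical residue name."""
    return THREE_TO_ONE[canonical.upper()]
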