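"""Built-in amino-acid constants and published reference statistics.

Two kinds of constants live here:

* Physical/biochemical constants — residue average mass M_X in Daltons
  (peptide-bonded residue, i.e. without water) and Davis' biosynthetic step
  counts B_X, an energetic-cost proxy.

* Published summary statistics of the high-resolution Ramachandran
  distributions derived from the protein geometry database PGD 1.1
  (1,153,791 residues): the MISE-optimal bin width Delta_X (degrees), the
  distribution peak P_X^max (percent), the observation count N_X, the
  modal-bin observation estimate W_X = P_X^max * N_X, and the mutational
  inertia I_X = M_X / W_X. These serve as reference fixtures: they let the
  table arithmetic, the common-grid rule and every correlation analysis run
  with no structure database attached ("table-only" mode).

Also defined: the seven replacement pairs shared by BLOSUM-family
substitution matrices, used as the reference set for pair-overlap scoring.
"""

from __future__ import annotations

import pandas as pd

# residue -> (mass M_X [Da], biosynthetic steps B_X,
#             Delta_X [deg], P_X^max [%], N_X, W_X, I_X)
_ROWS: dict[str, tuple[float, int, float, float, int, float, float]] = {
    "Ala": (71.079, 4, 1.176, 0.437, 113609, 496.654, 0.143),
    "Arg": (156.188, 10, 1.593, 0.265, 45373, 120.333, 1.298),
    "Asn": (114.104, 2, 2.535, 0.156, 46573, 72.701, 1.569),
    "Asp": (115.089, 1, 2.169, 0.192, 56963, 109.191, 1.054),
    "Cys": (103.139, 5, 2.951, 0.173, 15823, 27.298, 3.778),
    "Gln": (128.131, 2, 2.118, 0.307, 35633, 109.470, 1.170),
    "Glu": (129.116, 1, 1.748, 0.321, 48458, 155.431, 0.831),
    "Gly": (57.052, 5, 2.118, 0.124, 98983, 122.840, 0.464),
    "His": (137.141, 13, 2.609, 0.173, 27675, 47.910, 2.862),
    "Ile": (113.159, 7, 1.488, 0.285, 74768, 213.090, 0.531),
    "Leu": (113.159, 7, 1.463, 0.276, 116941, 322.560, 0.351),
    "Lys": (128.174, 10, 1.856, 0.276, 40135, 110.584, 1.159),
    "Met": (131.193, 7, 1.782, 0.284, 20968, 59.610, 2.201),
    "Phe": (147.177, 11, 2.169, 0.190, 56511, 107.242, 1.372),
    "Pro": (97.117, 4, 2.222, 0.110, 54555, 60.167, 1.614),
    "Ser": (87.078, 4, 1.978, 0.141, 66612, 93.593, 0.930),
    "Thr": (101.105, 6, 2.069, 0.178, 68557, 121.726, 0.831),
    "Trp": (186.213, 14, 2.687, 0.200, 21118, 42.340, 4.398),
    "Tyr": (163.176, 11, 2.400, 0.184, 48972, 90.250, 1.808),
    "Val": (99.133, 4, 1.622, 0.241, 95564, 230.082, 0.431),
}

_COLUMNS = ["mass", "b_steps", "delta_min", "p_max_percent", "n_obs", "w", "inertia"]


def reference_table() -> pd.DataFrame:
    """The full published reference table, one row per residue.

    Columns: mass (Da), b_steps, delta_min (deg), p_max_percent (%), n_obs,
    w (= p_max * n_obs, from unrounded p_max), inertia (= mass / w).
    """
    return pd.DataFrame.from_dict(_ROWS, orient="index", columns=_COLUMNS).rename_axis(
        "residue"
    )


def constants() -> pd.DataFrame:
    """Just the physical constants: mass and biosynthetic steps."""
    return reference_table()[["mass", "b_steps"]]


#: Replacement pairs defined by BLOSUM-family substitution matrices
#: (BLOSUM62/BLOSUM100): the canonical conservative substitutions.
BLOSUM_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("Asn", "Asp"),
        ("Phe", "Tyr"),
        ("Lys", "Arg"),
        ("Gln", "Glu"),
        ("Ile", "Val"),
        ("Met", "Leu"),
        ("Ser", "Thr"),
    ]
)
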