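"""Mutational inertia, substitution matrices, and the correlation analyses.

The mutational (replacement) inertia of residue X is

    I_X = M_X / W_X,      W_X = P_X^max * N_X,

mass per observation at the most probable backbone conformation: an
energetic-cost-over-frequency statistic hypothesised to track the
mutability of the residue, i.e. the diagonal score of a substitution
matrix (higher diagonal = more resistant to replacement). This module
builds the per-residue table, parses substitution matrices (NCBI
whitespace-table and AAindex lower-triangle formats), extracts mutability
diagonals and runs the correlation analyses: mass vs biosynthetic steps,
mass vs P_X^max over helix-former partitions, and the I_X-vs-mutability
survey over a matrix collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .residues import CANONICAL, ONE_TO_THREE, canonicalize, one_letter

#: AAindex lower-triangle residue order (one-letter).
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: C-beta branched residues; with Pro they form the backbone-restricted set.
CBETA_BRANCHED: frozenset[str] = frozenset({"Ile", "Thr", "Val"})


# ---------------------------------------------------------------------------
# Table arithmetic

def build_table(
    summaries: Mapping[str, tuple[int, float]] | pd.DataFrame,
    constants: pd.DataFrame,
    *,
    require_all: bool = True,
) -> pd.DataFrame:
    """Combine density summaries with physical constants into the full table.

    ``summaries`` maps residue -> (N_X, p_max fraction) (or a frame with
    columns ``n_obs`` and ``p_max_fraction``); ``constants`` has columns
    ``mass`` and ``b_steps``. All twenty residues must be present in both.
    Output columns: mass, b_steps, p_max_percent, n_obs, w, inertia with
    w = p_max * N and inertia = mass / w.
    """
    if isinstance(summaries, pd.DataFrame):
        summ = {
            res: (int(row["n_obs"]), float(row["p_max_fraction"]))
            for res, row in summaries.iterrows()
        }
    else:
        summ = {canonicalize(r): (int(n), float(p)) for r, (n, p) in summaries.items()}
    if require_all:
        missing = [r for r in CANONICAL if r not in summ or r not in constants.index]
        if missing:
            raise ValueError(f"missing residues: {missing}")
        wanted = list(CANONICAL)
    else:
        wanted = [r for r in CANONICAL if r in summ]
        missing = [r for r in wanted if r not in constants.index]
        if missing:
            raise ValueError(f"missing constants for: {missing}")
    rows = []
    for res in wanted:
        n_obs, p_max = summ[res]
        mass = float(constants.loc[res, "mass"])
        w = p_max * n_obs
        rows.append({
            "residue": res,
            "mass": mass,
            "b_steps": int(constants.loc[res, "b_steps"]),
            "p_max_percent": 100.0 * p_max,
            "n_obs": n_obs,
            "w": w,
            "inertia": mass / w if w > 0 else math.inf,
        })
    return pd.DataFrame(rows).set_index("residue")


def pearson(
    x: Sequence[float] | pd.Series,
    y: Sequence[float] | pd.Series,
    exclude: Iterable[str] | None = None,
) -> float:
    """Sample Pearson correlation, optionally excluding labelled entries.

    ``exclude`` requires both inputs to be label-indexed Series. At least
    three pairs must remain and both sides need nonzero variance.
    """
    if exclude is not None:
        if not isinstance(x, pd.Series) or not isinstance(y, pd.Series):
            raise TypeError("exclusion by label requires pandas Series inputs")
        keep = [i for i in x.index if i not in set(exclude)]
        x, y = x.loc[keep], y.loc[keep]
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size < 3:
        raise ValueError("need at least 3 paired values")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(xv, yv)[0])


@dataclass
class HelixPartition:
    """Strong/weak helix-former split and its mass-vs-P_max correlations."""

    threshold_percent: float
    strong: tuple[str, ...]
    weak: tuple[str, ...]
    r_overall: float | None
    r_strong: float | None
    r_weak: float | None
    r_cbeta_pro: float | None
    r_strong_excl: float | None
    r_weak_excl: float | None
    warnings: tuple[str, ...] = ()


def helix_former_partition(
    table: pd.DataFrame, threshold: float = 0.200
) -> HelixPartition:
    """Partition residues at P_X^max > ``threshold`` percent (strictly).

    Strict inequality puts a residue sitting exactly at the threshold in
    the weak set. Correlations of mass against P_X^max (percent) are
    computed overall, within each partition, over the backbone-restricted
    set (C-beta branched + Pro), and within each partition after removing
    its C-beta-branched members and Pro. Partitions with fewer than three
    members have their correlation omitted with a warning.
    """
    pmax = table["p_max_percent"]
    strong = tuple(r for r in table.index if pmax[r] > threshold)
    weak = tuple(r for r in table.index if r not in strong)
    restricted = CBETA_BRANCHED | {"Pro"}
    warnings: list[str] = []

    def corr(members: Sequence[str], name: str) -> float | None:
        if len(members) < 3:
            warnings.append(f"{name}: only {len(members)} members, correlation omitted")
            return None
        return pearson(table.loc[list(members), "mass"],
                       table.loc[list(members), "p_max_percent"])

    return HelixPartition(
        threshold_percent=threshold,
        strong=strong,
        weak=weak,
        r_overall=corr(list(table.index), "overall"),
        r_strong=corr(strong, "strong"),
        r_weak=corr(weak, "weak"),
        r_cbeta_pro=corr([r for r in table.index if r in restricted], "cbeta+pro"),
        r_strong_excl=corr([r for r in strong if r not in restricted], "strong-excl"),
        r_weak_excl=corr([r for r in weak if r not in restricted], "weak-excl"),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# Substitution matrices

@dataclass
class SubstitutionMatrix:
    """20 x 20 substitution score table; the diagonal is the mutability scale."""

    name: str
    scores: pd.DataFrame          # index/columns: canonical residue names
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [r for r in CANONICAL if r not in self.scores.index]
        if missing:
            raise ValueError(f"matrix {self.name}: missing residues {missing}")
        self.scores = self.scores.loc[list(CANONICAL), list(CANONICAL)].astype(float)
        if not np.allclose(self.scores.to_numpy(), self.scores.to_numpy().T):
            bad = np.argwhere(
                ~np.isclose(self.scores.to_numpy(), self.scores.to_numpy().T)
            )[0]
            raise ValueError(
                f"matrix {self.name}: asymmetric at "
                f"({CANONICAL[bad[0]]}, {CANONICAL[bad[1]]})"
            )


def mutability(matrix: SubstitutionMatrix) -> pd.Series:
    """The matrix diagonal, labelled by residue."""
    diag = pd.Series(
        np.diag(matrix.scores.to_numpy()), index=list(CANONICAL), name=matrix.name
    )
    return diag


def read_substitution_matrix(
    path: str | Path,
    format: str = "ncbi",
    *,
    name: str | None = None,
    aaindex_order: str = AAINDEX_ORDER,
) -> SubstitutionMatrix:
    """Parse a substitution matrix file.

    ``format='ncbi'``: '#'-comment lines, a header row of one-letter codes,
    then rows labelled by one-letter code; ambiguity columns (B, Z, X, *, J,
    U, O) are dropped; symmetry over the canonical 20 is verified.

    ``format='aaindex-lower-triangle'``: a numeric lower-triangular block
    (diagonal included) in ``aaindex_order`` row/column order; the upper
    triangle is mirrored.
    """
    path = Path(path)
    label = name if name is not None else path.stem
    if format == "ncbi":
        return _read_ncbi(path, label)
    if format == "aaindex-lower-triangle":
        return _read_aaindex_lt(path, label, aaindex_order)
    raise ValueError(f"unknown format: {format!r}")


def _read_ncbi(path: Path, name: str) -> SubstitutionMatrix:
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no matrix content")
    header = lines[0].split()
    rows: dict[str, dict[str, float]] = {}
    for ln in lines[1:]:
        fields = ln.split()
        row_label = fields[0]
        values = fields[1:]
        if len(values) != len(header):
            raise ValueError(f"{path}: row {row_label} has {len(values)} values, "
                             f"expected {len(header)}")
        rows[row_label] = dict(zip(header, (float(v) for v in values)))
    keep = [c for c in header if c in ONE_TO_THREE]
    missing = [c for c in map(one_letter, CANONICAL) if c not in keep or c not in rows]
    if missing:
        raise ValueError(
            f"{path}: missing canonical residue(s) "
            f"{[ONE_TO_THREE[m].capitalize() for m in missing]}"
        )
    frame = pd.DataFrame(
        {canonicalize(c): {canonicalize(r): rows[r][c] for r in keep} for c in keep}
    )
    return SubstitutionMatrix(name=name, scores=frame, provenance=f"ncbi:{path.name}")


def _read_aaindex_lt(path: Path, name: str, order: str) -> SubstitutionMatrix:
    values: list[float] = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        values.extend(float(v) for v in ln.split())
    n = len(order)
    if len(values) != n * (n + 1) // 2:
        raise ValueError(
            f"{path}: expected {n*(n+1)//2} lower-triangle values, got {len(values)}"
        )
    mat = np.zeros((n, n))
    it = iter(values)
    for i in range(n):
        for j in range(i + 1):
            mat[i, j] = mat[j, i] = next(it)
    labels = [canonicalize(c) for c in order]
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    return SubstitutionMatrix(name=name, scores=frame, provenance=f"aaindex:{path.name}")


def write_substitution_matrix(
    matrix: SubstitutionMatrix, path: str | Path, *, fmt: str = "%g"
) -> None:
    """Write a matrix in the NCBI whitespace-table layout (round-trippable)."""
    letters = [one_letter(r) for r in CANONICAL]
    with Path(path).open("w") as fh:
        fh.write(f"# {matrix.name}\n")
        fh.write("   " + "  ".join(letters) + "\n")
        for r, letter in zip(CANONICAL, letters):
            vals = "  ".join(fmt % matrix.scores.loc[r, c] for c in CANONICAL)
            fh.write(f"{letter}  {vals}\n")


def packaged_matrix_paths() -> list[Path]:
    """Paths of the synthetic NCBI-format matrix fixtures shipped in-package."""
    from importlib.resources import files

    data = files("ramastats.data")
    return sorted(
        Path(str(entry)) for entry in data.iterdir() if entry.name.endswith(".txt")
    )


# ---------------------------------------------------------------------------
# Correlation survey

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class SurveyResult:
    """I_X-vs-mutability survey over a substitution-matrix collection."""

    per_matrix: pd.DataFrame        # index matrix name; columns r, p, stars
    mean_r: float
    cross_correlation: pd.DataFrame  # (m+1) x (m+1), I_X first
    cross_stars: pd.DataFrame
    mean_pairwise_r: float | None    # mean R over unordered matrix pairs


def correlation_survey(
    inertia: pd.Series, matrices: Sequence[SubstitutionMatrix]
) -> SurveyResult:
    """Correlate the inertia scale against every matrix's mutability diagonal.

    Per matrix: Pearson R between I_X and the diagonal, with a two-sided
    t-test p-value rendered as significance stars (0.05 *, 0.01 **,
    0.001 ***). Also returned: the unweighted mean R over matrices, the full
    cross-correlation matrix among [I_X] + all mutability vectors (with
    stars), and the mean R over unordered matrix-matrix pairs (None for a
    single matrix).
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    inertia = inertia.reindex(list(CANONICAL))
    if inertia.isna().any():
        raise ValueError("inertia vector is missing residues")
    vectors = {"I_X": inertia.to_numpy(dtype=float)}
    rows = []
    for m in matrices:
        diag = mutability(m)
        r, p = stats.pearsonr(inertia.to_numpy(dtype=float), diag.to_numpy())
        rows.append({"matrix": m.name, "r": float(r), "p": float(p), "stars": _stars(p)})
        vectors[m.name] = diag.to_numpy()
    per_matrix = pd.DataFrame(rows).set_index("matrix")
    names = list(vectors)
    k = len(names)
    corr = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(vectors[names[i]], vectors[names[j]])
            corr[i, j] = corr[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    cross = pd.DataFrame(corr, index=names, columns=names)
    cross_stars = pd.DataFrame(
        [[_stars(pmat[i, j]) if i != j else "" for j in range(k)] for i in range(k)],
        index=names, columns=names,
    )
    mat_names = names[1:]
    if len(mat_names) > 1:
        pair_rs = [
            corr[i, j]
            for i in range(1, k)
            for j in range(i + 1, k)
        ]
        mean_pairwise = float(np.mean(pair_rs))
    else:
        mean_pairwise = None
    return SurveyResult(
        per_matrix=per_matrix,
        mean_r=float(per_matrix["r"].mean()),
        cross_correlation=cross,
        cross_stars=cross_stars,
        mean_pairwise_r=mean_pairwise,
    )
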