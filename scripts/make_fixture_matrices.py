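"""Regenerate the synthetic substitution-matrix fixtures in src/ramastats/data.

The fixtures are *synthetic* score tables in the NCBI whitespace-table
layout — symmetric 20x20 integer matrices with a positive diagonal — used
for format/round-trip tests and for exercising the correlation survey.
They are not derived from any alignment database.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ramastats.inertia import SubstitutionMatrix, write_substitution_matrix
from ramastats.residues import CANONICAL

OUT = Path(__file__).resolve().parents[1] / "src" / "ramastats" / "data"


def random_matrix(name: str, rng: np.random.Generator) -> SubstitutionMatrix:
    off = rng.integers(-4, 3, size=(20, 20))
    scores = np.tril(off) + np.tril(off, -1).T
    np.fill_diagonal(scores, rng.integers(4, 12, size=20))
    frame = pd.DataFrame(scores, index=list(CANONICAL), columns=list(CANONICAL))
    return SubstitutionMatrix(name=name, scores=frame, provenance="synthetic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(20170810)
    for i in range(1, 4):
        m = random_matrix(f"synthetic_{i}", rng)
        write_substitution_matrix(m, OUT / f"synthetic_{i}.txt", fmt="%d")
        print("wrote", OUT / f"synthetic_{i}.txt")


if __name__ == "__main__":
    main()
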