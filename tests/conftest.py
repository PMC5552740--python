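import numpy as np
import pytest

from ramastats import reference
from ramastats.dihedral_io import DihedralRecord


@pytest.fixture(scope="session")
def ref_table():
    return reference.reference_table()


@pytest.fixture(scope="session")
def small_dataset():
    """300 samples for each of the 20 residues, fixed master seed."""
    from ramastats.synthetic import default_profiles, generate_dataset

    profiles = default_profiles(300, master_seed=42)
    records, truth = generate_dataset(profiles, master_seed=42, compute_modal_mass=False)
    return records, truth


def make_records(residue: str, pairs) -> list[DihedralRecord]:
    return [DihedralRecord(residue, float(phi), float(psi)) for phi, psi in pairs]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
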