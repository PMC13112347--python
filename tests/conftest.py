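import numpy as np
import pytest

import zernipep as zp
from zernipep.fixtures import ContactSchedule, ToyDimerSpec, make_toy_dimer


@pytest.fixture(scope="session")
def toy_dimer():
    """8+8-residue poly-ALA dimer with a 6 Å interface."""
    return make_toy_dimer(ToyDimerSpec(n_residues=8, separation=6.0, seed=0))


@pytest.fixture(scope="session")
def param_dimer(toy_dimer):
    return zp.assign_parameters(toy_dimer)


@pytest.fixture(scope="session")
def small_complex():
    """8-residue target chain A with a 6-residue peptide chain B."""
    dimer = make_toy_dimer(
        ToyDimerSpec(n_residues=8, separation=6.0, seed=0, n_residues_b=6)
    )
    return zp.assign_parameters(dimer)


@pytest.fixture
def contact_schedule():
    occ = np.array([0.05, 0.05, 0.9, 0.9, 0.9, 0.9, 0.05, 0.05])
    return ContactSchedule(occ, n_frames=40, seed=1)


@pytest.fixture(scope="session")
def ala3_pdb():
    """Hand-written 3-residue poly-ALA PDB text."""
    lines = []
    serial = 0
    coords = {
        "N": (-1.2, 0.5, 0.0), "CA": (0.0, 0.0, 0.0),
        "C": (1.2, 0.5, 0.0), "O": (1.4, 1.6, 0.0), "CB": (0.0, 1.3, 0.9),
    }
    for i in range(3):
        for name, (x, y, z) in coords.items():
            serial += 1
            px = x + 3.8 * i
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA A{i+1:4d}    "
                f"{px:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{name[0]:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
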