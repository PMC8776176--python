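import numpy as np
import pandas as pd
import pytest

from pbflex import Ensemble, PBAlphabet


@pytest.fixture(scope="session")
def alphabet():
    return PBAlphabet.default()


def make_ca_ensemble(coords, first_resid=1):
    """Ensemble of CA-only frames from a (n_frames, n_atoms, 3) array."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * n_atoms,
            "resid": np.arange(first_resid, first_resid + n_atoms),
            "resname": ["ALA"] * n_atoms,
            "name": ["CA"] * n_atoms,
            "b_factor": np.zeros(n_atoms),
        }
    )
    return Ensemble(coords, atoms)


def make_backbone_ensemble(coords, first_resid=1):
    """Ensemble from (n_frames, n_res, 3, 3) N/CA/C coordinates."""
    coords = np.asarray(coords, dtype=float)
    n_frames, n_res = coords.shape[:2]
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * (n_res * 3),
            "resid": np.repeat(np.arange(first_resid, first_resid + n_res), 3),
            "resname": ["ALA"] * (n_res * 3),
            "name": ["N", "CA", "C"] * n_res,
            "b_factor": np.zeros(n_res * 3),
        }
    )
    return Ensemble(coords.reshape(n_frames, -1, 3), atoms)


@pytest.fixture()
def pentapeptide_pdb(tmp_path):
    """2-model PDB of a 5-residue CA trace (minimal multi-model fixture)."""
    lines = []
    rng = np.random.default_rng(5)
    for model in (1, 2):
        lines.append(f"MODEL     {model:4d}")
        for i in range(5):
            x, y, z = rng.uniform(0, 9, 3).round(3)
            lines.append(
                f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 10.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "penta.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
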