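"""File input/output: multi-model PDB, optional binary trajectories, PB-fasta.

Multi-model PDB (MODEL/ENDMDL) is the canonical ensemble format; XTC and
DCD trajectories with a PDB topology are supported as an optional adapter
behind the same :class:`~pbflex.ensemble.Ensemble` contract.  Per-frame PB
strings are serialised as "PB-fasta": one FASTA record per frame whose
sequence runs over the letters a..p plus ``Z`` for unassignable positions
(the dialect produced by PB assignment tools).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
import biotite.sequence.io.fasta as fasta_io

from .ensemble import Ensemble
from .errors import EnsembleFormatError

_ELEMENT_FROM_NAME = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _scan_model_atom_counts(path: Path) -> list[int]:
    """Atom counts per MODEL block of a PDB file (whole file = one model
    when no MODEL records are present)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")):
                current += 1
                if not saw_model:
                    in_model = True
    if in_model and (not saw_model or current):
        if not saw_model:
            counts.append(current)
    return counts or [current]


def read_ensemble(
    path,
    chain: Optional[str] = None,
    resid_range: Optional[tuple] = None,
    frame_spacing_ps: float = 100.0,
    topology=None,
) -> Ensemble:
    """Read a multi-model PDB (or XTC/DCD + PDB topology) into an Ensemble.

    Parameters
    ----------
    path:
        Multi-model PDB file, or an ``.xtc``/``.dcd`` trajectory when
        ``topology`` (a single-model PDB) is given.
    chain, resid_range:
        Optional selection applied after reading (inclusive residue range,
        author numbering).
    frame_spacing_ps:
        Time between frames, metadata only.

    Raises
    ------
    EnsembleFormatError
        If the file cannot be parsed, MODEL blocks disagree in atom count
        (the first offending model is named), or insertion codes occur.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    suffix = path.suffix.lower()
    if suffix in (".xtc", ".dcd"):
        ens = _read_binary_trajectory(path, topology, frame_spacing_ps)
    else:
        ens = _read_multimodel_pdb(path, frame_spacing_ps)
    if chain is not None or resid_range is not None:
        ens = ens.select(chain=chain, resid_range=resid_range)
    return ens


def _read_multimodel_pdb(path: Path, frame_spacing_ps: float) -> Ensemble:
    counts = _scan_model_atom_counts(path)
    if len(set(counts)) > 1:
        ref = counts[0]
        bad = next(i for i, c in enumerate(counts, start=1) if c != ref)
        raise EnsembleFormatError(
            f"{path}: MODEL {bad} has {counts[bad - 1]} atoms, "
            f"expected {ref} (models must share one atom table)"
        )
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="first")
        first = pdb.get_structure(
            model=1, altloc="first", extra_fields=["b_factor"]
        )
    except Exception as exc:  # biotite parse failure
        raise EnsembleFormatError(f"{path}: cannot parse PDB ({exc})") from exc
    if np.any(first.ins_code != ""):
        bad_res = first.res_id[first.ins_code != ""][0]
        raise EnsembleFormatError(
            f"{path}: insertion code at residue {bad_res} is not supported"
        )
    atoms = pd.DataFrame(
        {
            "chain": first.chain_id,
            "resid": first.res_id.astype(int),
            "resname": first.res_name,
            "name": first.atom_name,
            "b_factor": first.b_factor.astype(float),
        }
    )
    coords = stack.coord if stack.coord.ndim == 3 else stack.coord[None]
    return Ensemble(coords, atoms, frame_spacing_ps=frame_spacing_ps)


def _read_binary_trajectory(path: Path, topology, frame_spacing_ps: float) -> Ensemble:
    if topology is None:
        raise EnsembleFormatError(
            f"{path}: binary trajectories need a PDB topology file"
        )
    top = _read_multimodel_pdb(Path(topology), frame_spacing_ps)
    if path.suffix.lower() == ".xtc":
        from biotite.structure.io.xtc import XTCFile as TrajFile
    else:
        from biotite.structure.io.dcd import DCDFile as TrajFile
    traj = TrajFile.read(str(path))
    coords = traj.get_coord()
    if coords.shape[1] != top.n_atoms:
        raise EnsembleFormatError(
            f"{path}: trajectory has {coords.shape[1]} atoms, "
            f"topology has {top.n_atoms}"
        )
    return Ensemble(coords, top.atoms, frame_spacing_ps=frame_spacing_ps)


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an Ensemble as a multi-model PDB (coordinates to 1e-3 A)."""
    n = ensemble.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = ensemble.atoms["chain"].to_numpy(dtype="U4")
    template.res_id = ensemble.atoms["resid"].to_numpy(dtype=int)
    template.res_name = ensemble.atoms["resname"].to_numpy(dtype="U5")
    template.atom_name = ensemble.atoms["name"].to_numpy(dtype="U6")
    template.element = np.array(
        [
            _ELEMENT_FROM_NAME.get(a, a[:1])
            for a in ensemble.atoms["name"]
        ],
        dtype="U2",
    )
    template.hetero = np.array(
        [rn not in struc.info.amino_acid_names() for rn in template.res_name]
    )
    template.set_annotation(
        "b_factor", ensemble.atoms["b_factor"].to_numpy(dtype=float)
    )
    template.set_annotation("occupancy", np.ones(n))
    stack = struc.from_template(template, ensemble.coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# -- PB-fasta ----------------------------------------------------------------

def write_pb_fasta(pb_ensemble, path, label: str = "frame") -> None:
    """Serialise a PBEnsemble as one FASTA record per frame."""
    ff = fasta_io.FastaFile()
    letters = pb_ensemble.letters
    for i in range(letters.shape[0]):
        ff[f"{label}_{i + 1}"] = "".join(letters[i])
    ff.write(str(path))


def read_pb_fasta(path, first_resid: Optional[int] = None):
    """Read PB-fasta back into a :class:`~pbflex.alphabet.PBEnsemble`.

    Residue numbering restarts at ``first_resid`` (default 1).
    """
    from .alphabet import PBEnsemble, VALID_PB_CHARS

    ff = fasta_io.FastaFile.read(str(path))
    seqs = [str(s) for s in ff.values()]
    if not seqs:
        raise EnsembleFormatError(f"{path}: no records")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise EnsembleFormatError(f"{path}: records differ in length")
    bad = set("".join(seqs)) - VALID_PB_CHARS
    if bad:
        raise EnsembleFormatError(
            f"{path}: invalid PB letters {sorted(bad)}"
        )
    letters = np.array([list(s) for s in seqs], dtype="U1")
    start = 1 if first_resid is None else first_resid
    resids = np.arange(start, start + letters.shape[1])
    return PBEnsemble(letters=letters, resids=resids)


# -- track/table export ------------------------------------------------------

def write_track_tsv(track: pd.Series, path, value_name: Optional[str] = None) -> None:
    """Write a per-residue track as TSV (residue, value), fixed formatting."""
    name = value_name or track.name or "value"
    df = pd.DataFrame({"residue": track.index.to_numpy(), name: track.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    """Write a positions x letters matrix as CSV, fixed formatting."""
    matrix.to_csv(path, float_format="%.6f")
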