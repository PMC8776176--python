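"""The Protein Blocks structural alphabet and per-frame assignment.

Protein Blocks (PBs) are 16 local-backbone prototypes, labelled a..p,
each defined by the (phi, psi) dihedrals of five consecutive residues:

    (psi_{i-2}, phi_{i-1}, psi_{i-1}, phi_i, psi_i, phi_{i+1}, psi_{i+1},
     phi_{i+2})

with the assignment attributed to the central residue i.  Block m
approximates the alpha-helix core and block d the central beta-strand;
a-c are strand N-caps, e-f strand C-caps, k-l helix N-caps, n-p helix
C-caps, and a-j cover coil.  A residue's block is the prototype with the
smallest angular RMSD (360-degree wraparound) to its window; ties break
alphabetically.  Positions whose window is incomplete — the first two and
last two residues of a chain, or any window containing an undefined
dihedral — are marked ``Z`` and excluded from downstream frequency
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from ._angles import wrap_degrees, angular_rmsd
from .geometry import DihedralSeries

PB_LETTERS = tuple("abcdefghijklmnop")
UNASSIGNED = "Z"
VALID_PB_CHARS = set(PB_LETTERS) | {UNASSIGNED}

#: Structural reading of each block.
PB_CATEGORIES: Dict[str, str] = {
    "a": "beta-strand N-cap / coil",
    "b": "beta-strand N-cap / coil",
    "c": "beta-strand N-cap / coil",
    "d": "central beta-strand",
    "e": "beta-strand C-cap / coil",
    "f": "beta-strand C-cap / coil",
    "g": "coil",
    "h": "coil",
    "i": "coil",
    "j": "coil",
    "k": "alpha-helix N-cap",
    "l": "alpha-helix N-cap",
    "m": "alpha-helix core",
    "n": "alpha-helix C-cap",
    "o": "alpha-helix C-cap",
    "p": "alpha-helix C-cap",
}

_WINDOW_COLUMNS = [
    "psi_m2", "phi_m1", "psi_m1", "phi_0", "psi_0", "phi_p1", "psi_p1", "phi_p2",
]


@dataclass(frozen=True)
class PBAlphabet:
    """The 16 PB letters with their reference dihedral windows (degrees)."""

    letters: tuple = PB_LETTERS
    reference_angles: np.ndarray = None  # (16, 8)
    categories: Dict[str, str] = field(default_factory=lambda: dict(PB_CATEGORIES))

    @classmethod
    def default(cls) -> "PBAlphabet":
        """Load the canonical published prototype table shipped with pbflex."""
        with resources.files("pbflex.data").joinpath(
            "pb_reference_angles.tsv"
        ).open() as fh:
            table = pd.read_csv(fh, sep="\t", comment="#")
        table = table.set_index("pb").loc[list(PB_LETTERS)]
        angles = table[_WINDOW_COLUMNS].to_numpy(dtype=float)
        return cls(reference_angles=angles)

    def __post_init__(self) -> None:
        if self.reference_angles is None:
            raise ValueError("reference_angles are required; use PBAlphabet.default()")
        angles = np.asarray(self.reference_angles, dtype=float)
        if angles.shape != (16, 8):
            raise ValueError(f"expected a (16, 8) angle table, got {angles.shape}")
        if (angles <= -180.0).any() or (angles > 180.0).any():
            raise ValueError("reference angles outside (-180, 180]")
        object.__setattr__(self, "reference_angles", angles)

    def central_angles(self, letter: str) -> tuple:
        """(phi, psi) of the central residue of a letter's reference window."""
        row = self.reference_angles[PB_LETTERS.index(letter)]
        return float(row[3]), float(row[4])


@dataclass
class PBEnsemble:
    """Per-frame, per-position PB letters (a..p, or Z when unassignable)."""

    letters: np.ndarray  # (n_frames, n_positions) of single chars
    resids: np.ndarray  # (n_positions,) author residue numbers

    def __post_init__(self) -> None:
        self.letters = np.asarray(self.letters, dtype="U1")
        self.resids = np.asarray(self.resids)
        if self.letters.ndim != 2:
            raise ValueError("letters must be (n_frames, n_positions)")
        if self.letters.shape[1] != len(self.resids):
            raise ValueError("position axis does not match resids")
        bad = set(self.letters.ravel()) - VALID_PB_CHARS
        if bad:
            raise ValueError(f"invalid PB letters {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.letters.shape[0]

    @property
    def n_positions(self) -> int:
        return self.letters.shape[1]

    def subset_frames(self, index) -> "PBEnsemble":
        return PBEnsemble(letters=self.letters[index], resids=self.resids)


def assign_pb_window(
    window,
    alphabet: Optional[PBAlphabet] = None,
    metric: Optional[Callable] = None,
) -> str:
    """PB letter for one 8-dihedral window.

    ``window`` is the 8-vector (psi_{i-2} .. phi_{i+2}) in degrees; any
    undefined (NaN) entry yields ``Z``.  The letter is the argmin of the
    angular RMSD to the 16 prototypes; ties break alphabetically.  A
    custom dissimilarity ``metric(window, reference) -> float`` may be
    supplied for testing.
    """
    alphabet = alphabet or PBAlphabet.default()
    window = np.asarray(window, dtype=float)
    if window.shape != (8,):
        raise ValueError(f"window must have 8 dihedrals, got {window.shape}")
    if not np.isfinite(window).all():
        return UNASSIGNED
    metric = metric or angular_rmsd
    distances = [metric(window, ref) for ref in alphabet.reference_angles]
    return alphabet.letters[int(np.argmin(distances))]


def _windows_from_dihedrals(dihedrals: DihedralSeries) -> np.ndarray:
    """Stack the 8-dihedral window of every position: (F, R, 8), NaN-padded."""
    phi, psi = dihedrals.phi, dihedrals.psi
    n_frames, n_res = phi.shape
    pad = np.full((n_frames, 2), np.nan)
    phi_p = np.concatenate([pad, phi, pad], axis=1)
    psi_p = np.concatenate([pad, psi, pad], axis=1)
    i = np.arange(n_res) + 2  # index of the central residue in padded arrays
    return np.stack(
        [
            psi_p[:, i - 2], phi_p[:, i - 1], psi_p[:, i - 1],
            phi_p[:, i], psi_p[:, i],
            phi_p[:, i + 1], psi_p[:, i + 1], phi_p[:, i + 2],
        ],
        axis=2,
    )


def assign_ensemble(
    dihedrals: DihedralSeries,
    alphabet: Optional[PBAlphabet] = None,
    chunk_frames: int = 256,
) -> PBEnsemble:
    """Sliding-window PB assignment of every frame.

    Positions 1-2 and n-1, n (and any position whose window contains an
    undefined dihedral) come out as ``Z``.  Assignment is deterministic
    and frame-independent.
    """
    alphabet = alphabet or PBAlphabet.default()
    if dihedrals.n_residues < 5:
        raise ValueError(
            f"need at least 5 residues for PB assignment, "
            f"got {dihedrals.n_residues}"
        )
    windows = _windows_from_dihedrals(dihedrals)  # (F, R, 8)
    refs = alphabet.reference_angles  # (16, 8)
    letters_arr = np.array(alphabet.letters, dtype="U1")
    n_frames, n_res = windows.shape[:2]
    out = np.full((n_frames, n_res), UNASSIGNED, dtype="U1")
    for start in range(0, n_frames, chunk_frames):
        block = windows[start : start + chunk_frames]  # (f, R, 8)
        complete = np.isfinite(block).all(axis=2)  # (f, R)
        diff = wrap_degrees(block[:, :, None, :] - refs[None, None, :, :])
        rmsd = np.sqrt(np.mean(diff**2, axis=3))  # (f, R, 16)
        best = letters_arr[np.argmin(rmsd, axis=2)]
        out[start : start + chunk_frames][complete] = best[complete]
    return PBEnsemble(letters=out, resids=dihedrals.resids)
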