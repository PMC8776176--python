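"""In-memory container for a conformational ensemble.

An :class:`Ensemble` is an ordered set of models (MD snapshots or PDB
MODEL blocks) sharing one atom identity table: coordinates are a
``(n_frames, n_atoms, 3)`` array in Angstrom, and per-atom metadata
(chain, residue number in author numbering, residue name, atom name,
B-factor) live in a pandas DataFrame.  Frame spacing is carried as
metadata (default 100 ps, the usual MD snapshot interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, SelectionError

#: Columns of the atom table, in order.
ATOM_COLUMNS = ["chain", "resid", "resname", "name", "b_factor"]


@dataclass
class Ensemble:
    """Multi-frame coordinate set with a shared atom table.

    Parameters
    ----------
    coords:
        ``(n_frames, n_atoms, 3)`` float array, Angstrom.
    atoms:
        DataFrame with columns ``chain, resid, resname, name, b_factor``;
        one row per atom, identical identity/order for every frame.
    frame_spacing_ps:
        Time between successive frames in picoseconds (metadata only).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_spacing_ps: float = 100.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                f"atom table has {len(self.atoms)} rows but coords carry "
                f"{self.coords.shape[1]} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates contain non-finite values")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table lacks columns {missing}")
        self.atoms = self.atoms.reset_index(drop=True)

    # -- basic shape ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def resids(self) -> np.ndarray:
        """Unique residue numbers, in order of first appearance."""
        return pd.unique(self.atoms["resid"].to_numpy())

    @property
    def n_residues(self) -> int:
        return len(self.resids)

    # -- selection ------------------------------------------------------
    def select(
        self,
        chain: Optional[str] = None,
        resid_range: Optional[tuple] = None,
        atom_names: Optional[Sequence[str]] = None,
    ) -> "Ensemble":
        """Subset by chain, inclusive residue range and/or atom names."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        if resid_range is not None:
            lo, hi = resid_range
            r = self.atoms["resid"].to_numpy()
            mask &= (r >= lo) & (r <= hi)
        if atom_names is not None:
            mask &= self.atoms["name"].isin(list(atom_names)).to_numpy()
        if not mask.any():
            raise SelectionError(
                f"selection (chain={chain!r}, resid_range={resid_range!r}, "
                f"atom_names={atom_names!r}) matches no atoms"
            )
        return Ensemble(
            self.coords[:, mask], self.atoms.loc[mask, :],
            frame_spacing_ps=self.frame_spacing_ps,
        )

    def discard_burnin(self, n_frames: int) -> "Ensemble":
        """Drop the first ``n_frames`` frames (equilibration burn-in)."""
        if n_frames < 0 or n_frames >= self.n_frames:
            raise ValueError(
                f"cannot discard {n_frames} of {self.n_frames} frames"
            )
        if n_frames == 0:
            return self
        return Ensemble(
            self.coords[n_frames:], self.atoms,
            frame_spacing_ps=self.frame_spacing_ps,
        )

    # -- derived coordinate views ---------------------------------------
    def ca_view(self) -> tuple[np.ndarray, np.ndarray]:
        """(resids, coords) for Cα atoms: ``(n_res,), (n_frames, n_res, 3)``."""
        mask = (self.atoms["name"] == "CA").to_numpy()
        if not mask.any():
            raise SelectionError("ensemble contains no CA atoms")
        return self.atoms.loc[mask, "resid"].to_numpy(), self.coords[:, mask]

    def ca_bfactors(self) -> pd.Series:
        """File B-factors of the Cα atoms, indexed by residue number."""
        mask = (self.atoms["name"] == "CA").to_numpy()
        sub = self.atoms.loc[mask]
        return pd.Series(
            sub["b_factor"].to_numpy(), index=sub["resid"].to_numpy(),
            name="b_factor",
        )

    def backbone_view(self) -> tuple[np.ndarray, np.ndarray]:
        """(resids, coords) of N/CA/C per residue.

        Returns coordinates shaped ``(n_frames, n_residues, 3, 3)`` with the
        middle axis ordered N, CA, C.  Raises :class:`GeometryError` naming
        the first residue lacking a backbone atom.
        """
        resids = self.resids
        idx = np.empty((len(resids), 3), dtype=int)
        names = self.atoms["name"].to_numpy()
        rid = self.atoms["resid"].to_numpy()
        for i, res in enumerate(resids):
            for j, at in enumerate(("N", "CA", "C")):
                hits = np.flatnonzero((rid == res) & (names == at))
                if len(hits) == 0:
                    raise GeometryError(
                        f"residue {res} lacks backbone atom {at}"
                    )
                idx[i, j] = hits[0]
        return resids, self.coords[:, idx.reshape(-1)].reshape(
            self.n_frames, len(resids), 3, 3
        )


def concatenate(ensembles: Sequence[Ensemble]) -> Ensemble:
    """Pool replicate ensembles frame-wise (identical atom tables required)."""
    if not ensembles:
        raise ValueError("nothing to concatenate")
    first = ensembles[0]
    for i, e in enumerate(ensembles[1:], start=2):
        if not first.atoms[ATOM_COLUMNS[:4]].equals(e.atoms[ATOM_COLUMNS[:4]]):
            raise ValueError(f"replicate {i} has a different atom identity table")
    return Ensemble(
        np.concatenate([e.coords for e in ensembles], axis=0),
        first.atoms,
        frame_spacing_ps=first.frame_spacing_ps,
    )
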