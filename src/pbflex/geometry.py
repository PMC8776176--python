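"""Backbone geometry: dihedrals, superposition, fluctuations, contacts.

Dihedral angles follow the IUPAC convention, reported in degrees on
(-180, 180]; phi_i is C(i-1)-N(i)-CA(i)-C(i) and psi_i is
N(i)-CA(i)-C(i)-N(i+1), so phi of the first residue and psi of the last
are undefined (NaN).  Superposition is the least-squares (Kabsch) fit;
RMSF is computed on Cα atoms after one alignment pass against the
ensemble-average structure.  A NeRF chain builder converts prescribed
(phi, psi) back into ideal-geometry backbone coordinates, which makes the
dihedral computation invertible and testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from ._angles import wrap_degrees
from .ensemble import Ensemble
from .errors import GeometryError, SelectionError

# Ideal backbone internal coordinates (Engh & Huber values), Angstrom/degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0

#: Conversion from RMSF (A) to a crystallographic B-factor (A^2).
B_FROM_MSF = 8.0 * np.pi**2 / 3.0


@dataclass
class DihedralSeries:
    """Per-frame, per-residue (phi, psi) in degrees; NaN = undefined."""

    phi: np.ndarray  # (n_frames, n_residues)
    psi: np.ndarray  # (n_frames, n_residues)
    resids: np.ndarray  # (n_residues,)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.resids = np.asarray(self.resids)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi shapes differ")
        if self.phi.shape[1] != len(self.resids):
            raise ValueError("residue axis does not match resids")
        for name, arr in (("phi", self.phi), ("psi", self.psi)):
            defined = arr[np.isfinite(arr)]
            if defined.size and (
                (defined <= -180.0).any() or (defined > 180.0).any()
            ):
                raise ValueError(f"{name} angles outside (-180, 180]")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC convention, float64.

    Vectorized over leading axes.  (Computed in double precision; generic
    structure toolkits often work in float32, which is too coarse for the
    1e-4 degree round-trip guarantees the synthetic generator relies on.)
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def compute_dihedrals(ensemble: Ensemble) -> DihedralSeries:
    """Backbone (phi, psi) for every residue of every frame.

    Requires N, CA, C for every residue; raises :class:`GeometryError`
    naming the first residue with a missing backbone atom.  Chain termini
    are flagged NaN (phi of the first residue, psi of the last).
    """
    resids, bb = ensemble.backbone_view()  # (F, R, 3, 3); N, CA, C
    n_frames, n_res = bb.shape[:2]
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    if n_res >= 2:
        # phi_i: C(i-1), N(i), CA(i), C(i)
        phi[:, 1:] = dihedral_angle(
            bb[:, :-1, 2], bb[:, 1:, 0], bb[:, 1:, 1], bb[:, 1:, 2]
        )
        # psi_i: N(i), CA(i), C(i), N(i+1)
        psi[:, :-1] = dihedral_angle(
            bb[:, :-1, 0], bb[:, :-1, 1], bb[:, :-1, 2], bb[:, 1:, 0]
        )
    phi[np.isfinite(phi)] = wrap_degrees(phi[np.isfinite(phi)])
    psi[np.isfinite(psi)] = wrap_degrees(psi[np.isfinite(psi)])
    return DihedralSeries(phi=phi, psi=psi, resids=resids)


# -- superposition ----------------------------------------------------------

def kabsch_fit(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation/translation mapping ``mobile`` onto ``reference``.

    Returns ``(rotation_matrix, translation)`` such that
    ``mobile @ R.T + t`` superposes onto the reference.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    R = rot.as_matrix()
    t = cr - cm @ R.T
    return R, t


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD (A) after least-squares superposition of two point sets."""
    R, t = kabsch_fit(coords_b, coords_a)
    fitted = coords_b @ R.T + t
    return float(np.sqrt(np.mean(np.sum((coords_a - fitted) ** 2, axis=1))))


def rmsf(
    ensemble: Ensemble,
    reference: str = "mean",
    unit: str = "angstrom",
) -> pd.Series:
    """Per-residue Cα root-mean-square fluctuation.

    Each frame is superposed (Kabsch) onto the reference — the
    ensemble-average Cα structure by default, or the first frame
    (``reference="first"``).  With the mean reference the mean is
    recomputed once after alignment.  ``unit`` is ``"angstrom"`` or
    ``"nm"``.

    A single-frame ensemble yields an all-zero track with a warning.
    """
    if unit not in ("angstrom", "nm"):
        raise ValueError(f"unknown unit {unit!r}")
    resids, ca = ensemble.ca_view()  # (F, R, 3)
    if ca.shape[0] < 2:
        warnings.warn("RMSF of a single-frame ensemble is zero everywhere")
        track = np.zeros(ca.shape[1])
        return pd.Series(track, index=resids, name="rmsf")
    ref = ca.mean(axis=0) if reference == "mean" else ca[0]
    aligned = np.empty_like(ca)
    for f in range(ca.shape[0]):
        R, t = kabsch_fit(ca[f], ref)
        aligned[f] = ca[f] @ R.T + t
    center = aligned.mean(axis=0)
    track = np.sqrt(np.mean(np.sum((aligned - center) ** 2, axis=2), axis=0))
    if unit == "nm":
        track = track / 10.0
    return pd.Series(track, index=resids, name="rmsf")


def bfactor_from_rmsf(rmsf_value):
    """Crystallographic B-factor (A^2) equivalent to an RMSF (A).

    B = (8 pi^2 / 3) RMSF^2, the standard isotropic relation; used only
    for side-by-side comparison with file B-factor columns.
    """
    r = np.asarray(rmsf_value, dtype=float)
    if (r < 0).any():
        raise ValueError("RMSF must be non-negative")
    b = B_FROM_MSF * r**2
    if isinstance(rmsf_value, pd.Series):
        return pd.Series(b, index=rmsf_value.index, name="b_factor")
    return b if b.ndim else float(b)


# -- contacts ---------------------------------------------------------------

@dataclass
class ContactPersistence:
    """Fraction of frames in contact, overall and per partner residue."""

    overall: float
    per_residue: pd.Series  # indexed by partner residue number

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.per_residue.index.to_numpy(),
                "fraction": self.per_residue.to_numpy(),
            }
        )


def contact_persistence(
    ensemble: Ensemble,
    site_mask: np.ndarray,
    partner_mask: np.ndarray,
    cutoff: float = 3.0,
) -> ContactPersistence:
    """Persistence of a contact between two atom selections.

    ``site_mask``/``partner_mask`` are boolean arrays over the ensemble's
    atoms (build them with :func:`atom_mask`).  A frame counts as "in
    contact" when the minimum inter-selection distance is at or below
    ``cutoff`` (A; default 3.0, a typical ion-coordination distance).
    The per-residue breakdown applies the same rule per partner residue.
    """
    site_mask = np.asarray(site_mask, dtype=bool)
    partner_mask = np.asarray(partner_mask, dtype=bool)
    if not site_mask.any() or not partner_mask.any():
        raise SelectionError("contact selections must be non-empty")
    site = ensemble.coords[:, site_mask]
    partner = ensemble.coords[:, partner_mask]
    partner_resids = ensemble.atoms.loc[partner_mask, "resid"].to_numpy()
    n_frames = ensemble.n_frames
    dmin = np.empty((n_frames, partner.shape[1]))
    for f in range(n_frames):
        dmin[f] = cdist(site[f], partner[f]).min(axis=0)
    in_contact = dmin <= cutoff
    overall = float(np.mean(in_contact.any(axis=1)))
    rows = {}
    for res in pd.unique(partner_resids):
        cols = partner_resids == res
        rows[res] = float(np.mean(in_contact[:, cols].any(axis=1)))
    per_res = pd.Series(rows, name="contact_fraction")
    return ContactPersistence(overall=overall, per_residue=per_res)


def atom_mask(
    ensemble: Ensemble,
    chain: Optional[str] = None,
    resids=None,
    atom_names=None,
) -> np.ndarray:
    """Boolean atom selection over an ensemble's atom table."""
    mask = np.ones(ensemble.n_atoms, dtype=bool)
    if chain is not None:
        mask &= (ensemble.atoms["chain"] == chain).to_numpy()
    if resids is not None:
        mask &= ensemble.atoms["resid"].isin(np.atleast_1d(resids)).to_numpy()
    if atom_names is not None:
        mask &= ensemble.atoms["name"].isin(list(atom_names)).to_numpy()
    return mask


# -- NeRF chain building ----------------------------------------------------

def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Position the fourth atom at given internal coordinates (NeRF)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    phi: np.ndarray,
    psi: np.ndarray,
    omega: float = OMEGA_TRANS,
) -> np.ndarray:
    """Backbone N/CA/C coordinates realising prescribed (phi, psi).

    ``phi[0]`` and ``psi[-1]`` are ignored (undefined at termini; NaN is
    accepted there).  Bond lengths/angles are ideal values and the peptide
    bond is planar trans (omega = 180 deg) unless overridden.  Returns an
    ``(n_residues, 3, 3)`` array ordered N, CA, C.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be 1-D arrays of equal length")
    n_res = len(phi)
    if n_res < 2:
        raise ValueError("need at least 2 residues to build a chain")
    interior_phi = phi[1:]
    interior_psi = psi[:-1]
    if not (np.isfinite(interior_phi).all() and np.isfinite(interior_psi).all()):
        raise GeometryError("NaN dihedral inside the chain")

    coords = np.empty((n_res, 3, 3))
    # first residue in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place_atom(
            n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[i - 1]
        )
        ca_i = _place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = _place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        coords[i] = (n_i, ca_i, c_i)
    return coords
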