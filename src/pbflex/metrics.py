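"""Per-position PB statistics: frequency profiles, Neq, deltas, exports.

The central quantities:

* ``f_x`` — the frequency of block x at a position, over the non-Z frames.
* ``Neq = exp(-sum_x f_x ln f_x)`` — the equivalent number of PBs, i.e.
  the exponential of the Shannon entropy (natural log) of the per-position
  PB distribution.  1 means a single block is ever observed (rigid);
  16 means all blocks appear uniformly (random coil).
* ``dPB = sum_x |f_x^A - f_x^B|`` — the L1 distance between the PB
  distributions of two systems at one position, in [0, 2].
* ``dNeq = |Neq_A - Neq_B|``.

Flexibility classes follow the Neq thresholds used for disorder scaling:
Neq > 8 disordered, 6 < Neq <= 8 highly flexible, 3 <= Neq <= 6 flexible
("around 4" marks inherent flexibility), Neq < 3 rigid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .alphabet import PB_LETTERS, PBEnsemble

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-6

FLEX_CLASSES = ("rigid", "flexible", "highly_flexible", "disordered")

#: Neq class boundaries: disordered above 8, highly flexible above 6,
#: flexible from 3 up, rigid below 3.
NEQ_DISORDERED = 8.0
NEQ_HIGHLY_FLEXIBLE = 6.0
NEQ_FLEXIBLE = 3.0


@dataclass
class PBProfile:
    """Positions x 16 PB frequency matrix with contributing-frame counts.

    Rows sum to 1 except where ``counts == 0`` (no assignable frame at the
    position); such rows are zero and flagged empty.
    """

    frequencies: np.ndarray  # (n_positions, 16)
    counts: np.ndarray  # (n_positions,) non-Z frames per position
    resids: np.ndarray  # (n_positions,)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.resids = np.asarray(self.resids)
        if self.frequencies.shape != (len(self.resids), 16):
            raise ValueError("frequencies must be (n_positions, 16)")
        if (self.frequencies < 0).any() or (self.frequencies > 1).any():
            raise ValueError("frequencies outside [0, 1]")
        sums = self.frequencies.sum(axis=1)
        occupied = self.counts > 0
        if not np.allclose(sums[occupied], 1.0, atol=1e-9):
            raise ValueError("occupied rows must sum to 1")

    @property
    def n_positions(self) -> int:
        return len(self.resids)

    @property
    def empty(self) -> np.ndarray:
        """Boolean mask of positions with no assignable frame."""
        return self.counts == 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.frequencies, index=self.resids, columns=list(PB_LETTERS)
        )
        df.index.name = "residue"
        return df

    def row(self, resid) -> np.ndarray:
        i = np.flatnonzero(self.resids == resid)
        if len(i) == 0:
            raise KeyError(f"residue {resid} not in profile")
        return self.frequencies[i[0]]

    def neq_track(self) -> pd.Series:
        """Per-position Neq (NaN at empty positions)."""
        values = np.full(self.n_positions, np.nan)
        for i in range(self.n_positions):
            if self.counts[i] > 0:
                values[i] = neq(self.frequencies[i])
        return pd.Series(values, index=self.resids, name="neq")


def pb_frequencies(ensemble: PBEnsemble) -> PBProfile:
    """Per-position PB frequencies ``f_x`` over the non-Z frames.

    Z frames are dropped from the denominator (never a 17th category);
    positions where every frame is Z come out as empty rows.
    """
    letters = ensemble.letters
    n_pos = ensemble.n_positions
    freqs = np.zeros((n_pos, 16))
    counts = np.zeros(n_pos, dtype=int)
    for j, letter in enumerate(PB_LETTERS):
        freqs[:, j] = (letters == letter).sum(axis=0)
    counts = freqs.sum(axis=1).astype(int)
    occupied = counts > 0
    freqs[occupied] /= counts[occupied, None]
    if (~occupied).any():
        logger.warning(
            "%d position(s) have no assignable frame and are flagged empty",
            int((~occupied).sum()),
        )
    return PBProfile(frequencies=freqs, counts=counts, resids=ensemble.resids)


def _check_normalized(row: np.ndarray, what: str) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if row.shape != (16,) and row.ndim != 1:
        raise ValueError(f"{what} must be a 1-D frequency vector")
    if (row < 0).any():
        raise ValueError(f"{what} has negative entries")
    if abs(row.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"{what} sums to {row.sum():.6g}, expected 1")
    return row


def neq(frequencies) -> float:
    """Equivalent number of PBs: exp of the Shannon entropy (natural log).

    Accepts any normalized frequency vector (0 ln 0 = 0 by convention);
    the result lies in [1, len(frequencies)].
    """
    f = _check_normalized(frequencies, "frequency row")
    nz = f[f > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def classify_flexibility(neq_value: float) -> str:
    """Flexibility class of a position from its Neq."""
    if not np.isfinite(neq_value) or not (1.0 - 1e-9 <= neq_value <= 16.0 + 1e-9):
        raise ValueError(f"Neq {neq_value!r} outside [1, 16]")
    if neq_value > NEQ_DISORDERED:
        return "disordered"
    if neq_value > NEQ_HIGHLY_FLEXIBLE:
        return "highly_flexible"
    if neq_value >= NEQ_FLEXIBLE:
        return "flexible"
    return "rigid"


@dataclass
class FlexProfile:
    """Per-position scalar tracks: Neq, class, optional RMSF/B-factor."""

    neq: pd.Series  # indexed by residue number
    flex_class: pd.Series
    rmsf: Optional[pd.Series] = None
    b_factor: Optional[pd.Series] = None
    low_confidence: Optional[pd.Series] = None

    @property
    def resids(self) -> np.ndarray:
        return self.neq.index.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        cols = {"neq": self.neq, "flex_class": self.flex_class}
        if self.rmsf is not None:
            cols["rmsf"] = self.rmsf
        if self.b_factor is not None:
            cols["b_factor"] = self.b_factor
        if self.low_confidence is not None:
            cols["low_confidence"] = self.low_confidence
        df = pd.DataFrame(cols)
        df.index.name = "residue"
        return df


def flex_profile(
    profile: PBProfile,
    rmsf: Optional[pd.Series] = None,
    b_factor: Optional[pd.Series] = None,
    min_count: int = 10,
) -> FlexProfile:
    """Assemble the per-position flexibility tracks from a PB profile.

    Positions with fewer than ``min_count`` contributing frames are
    flagged low-confidence; empty positions carry NaN Neq and no class.
    Optional RMSF/B-factor tracks are joined on residue number.
    """
    track = profile.neq_track()
    classes = pd.Series(
        [
            classify_flexibility(v) if np.isfinite(v) else ""
            for v in track.to_numpy()
        ],
        index=track.index,
        name="flex_class",
    )
    low = pd.Series(
        profile.counts < min_count, index=track.index, name="low_confidence"
    )
    joined_rmsf = rmsf.reindex(track.index) if rmsf is not None else None
    joined_b = b_factor.reindex(track.index) if b_factor is not None else None
    return FlexProfile(
        neq=track, flex_class=classes, rmsf=joined_rmsf,
        b_factor=joined_b, low_confidence=low,
    )


def delta_neq(a, b) -> pd.Series:
    """Per-position |Neq_A - Neq_B| on the shared residue numbering."""
    track_a = a.neq if isinstance(a, FlexProfile) else a
    track_b = b.neq if isinstance(b, FlexProfile) else b
    shared = track_a.index.intersection(track_b.index)
    shared = shared[
        np.isfinite(track_a[shared].to_numpy())
        & np.isfinite(track_b[shared].to_numpy())
    ]
    if len(shared) == 0:
        raise ValueError("profiles share no assignable positions")
    return pd.Series(
        np.abs(track_a[shared].to_numpy() - track_b[shared].to_numpy()),
        index=shared,
        name="delta_neq",
    )


def delta_pb(row_a, row_b) -> Tuple[float, np.ndarray]:
    """L1 distance between two per-position PB distributions.

    Returns ``(dPB, per_letter)`` where ``per_letter`` is the 16-vector of
    absolute frequency differences (so statements like "an 80% difference
    for block h" can be read off directly).  dPB is 0 for identical rows
    and 2 for disjoint support.
    """
    fa = _check_normalized(row_a, "first row")
    fb = _check_normalized(row_b, "second row")
    per_letter = np.abs(fa - fb)
    return float(per_letter.sum()), per_letter


def delta_pb_profile(a: PBProfile, b: PBProfile) -> pd.DataFrame:
    """Per-position dPB between two systems, on positions assignable in both.

    Returns a DataFrame indexed by residue with ``delta_pb`` plus one
    ``d_<letter>`` column per block.
    """
    shared, ia, ib = np.intersect1d(a.resids, b.resids, return_indices=True)
    usable = (a.counts[ia] > 0) & (b.counts[ib] > 0)
    if not usable.any():
        raise ValueError("no position is assignable in both systems")
    rows = []
    for i, j in zip(ia[usable], ib[usable]):
        total, per_letter = delta_pb(a.frequencies[i], b.frequencies[j])
        rows.append([total, *per_letter])
    df = pd.DataFrame(
        rows,
        index=shared[usable],
        columns=["delta_pb"] + [f"d_{x}" for x in PB_LETTERS],
    )
    df.index.name = "residue"
    return df


def occurrence_map(profile: PBProfile, region: Tuple[int, int]) -> pd.DataFrame:
    """Position x letter frequency sub-matrix for an inclusive residue range.

    Rendering-ready: positions as rows, the letters a..p as columns (the
    standard orientation for PB occurrence heatmaps).
    """
    start, end = region
    mask = (profile.resids >= start) & (profile.resids <= end)
    if not mask.any() or start < profile.resids.min() or end > profile.resids.max():
        raise ValueError(
            f"region {start}-{end} outside profile "
            f"({profile.resids.min()}-{profile.resids.max()})"
        )
    return profile.to_frame().loc[profile.resids[mask]]


def logo_export(profile: PBProfile, region: Tuple[int, int]) -> pd.DataFrame:
    """Per-position letter-height table for sequence-logo rendering.

    Heights are the relative frequencies themselves (not information
    content), sorted by descending frequency within each position; zero
    frequencies are dropped and empty positions omitted with a log note.
    """
    sub = occurrence_map(profile, region)
    records = []
    for resid, row in sub.iterrows():
        if row.sum() == 0:
            logger.warning("residue %s has no assignable frame; omitted from logo", resid)
            continue
        for letter, height in row.sort_values(ascending=False).items():
            if height > 0:
                records.append((resid, letter, float(height)))
    return pd.DataFrame(records, columns=["residue", "pb", "height"])
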