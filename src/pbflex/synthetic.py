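"""Ground-truth synthetic ensembles with the statistics the analysis assumes.

The generator replaces MD trajectories in tests: every position is given a
target categorical distribution over the 16 PBs, and frames are sampled
from those targets.  Three modes trade realism against exactness:

* ``string`` — letters drawn i.i.d. per frame and position; the empirical
  frequency profile converges to the targets, making analytic Neq / dPB
  values exactly recoverable in the large-frame limit.
* ``geometry`` — each drawn letter is realised as the central (phi, psi)
  of its reference window plus wrapped Gaussian noise (sigma degrees).
  Because adjacent PB windows share dihedrals, arbitrary per-position
  mixtures are not simultaneously realisable: letters are therefore drawn
  once per homogeneous segment (a run of positions sharing a target) per
  frame, which keeps windows locally consistent.
* ``coordinate`` — geometry mode plus NeRF chain building with ideal bond
  geometry and trans peptide bonds, yielding backbone coordinates and,
  through the I/O layer, a multi-model PDB.

The sampling design mirrors replicated MD production: ``n_replicates``
(default 11) independent runs whose RNG streams derive from
``seed + replicate index``.  Defaults (pure block d for strand cores,
sigma = 10 degrees of dihedral noise, 11 replicates) emulate the rigid
immunoglobulin-fold sampling the analysis was built for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .alphabet import PB_LETTERS, PBAlphabet, PBEnsemble
from ._angles import wrap_degrees
from .ensemble import Ensemble
from .geometry import DihedralSeries, build_backbone

LETTER_INDEX = {letter: i for i, letter in enumerate(PB_LETTERS)}

DistributionLike = Union[str, Dict[str, float], np.ndarray, Sequence[float]]


def distribution(spec: DistributionLike) -> np.ndarray:
    """Normalize a distribution spec into a 16-vector over a..p.

    Accepts a single letter (``"d"`` -> pure d), a ``{letter: prob}``
    mapping, or a full 16-vector.
    """
    if isinstance(spec, str):
        if spec not in LETTER_INDEX:
            raise ValueError(f"unknown PB letter {spec!r}")
        vec = np.zeros(16)
        vec[LETTER_INDEX[spec]] = 1.0
        return vec
    if isinstance(spec, dict):
        vec = np.zeros(16)
        for letter, p in spec.items():
            if letter not in LETTER_INDEX:
                raise ValueError(f"unknown PB letter {letter!r}")
            vec[LETTER_INDEX[letter]] = float(p)
    else:
        vec = np.asarray(spec, dtype=float)
        if vec.shape != (16,):
            raise ValueError(f"distribution vector must have 16 entries, got {vec.shape}")
    if (vec < 0).any():
        raise ValueError("negative probabilities")
    total = vec.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"distribution sums to {total:.6g}, expected 1")
    return vec / total


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic system.

    ``targets`` is the (n_positions, 16) matrix of per-position PB
    distributions over residues ``first_resid .. first_resid + n - 1``.
    """

    targets: np.ndarray
    first_resid: int = 1
    n_frames: int = 100
    n_replicates: int = 11
    sigma: float = 10.0
    mode: str = "string"
    seed: int = 0

    def __post_init__(self) -> None:
        targets = np.asarray(self.targets, dtype=float)
        if targets.ndim != 2 or targets.shape[1] != 16:
            raise ValueError("targets must be (n_positions, 16)")
        if (targets < 0).any() or not np.allclose(targets.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each target row must be a normalized distribution")
        object.__setattr__(self, "targets", targets)
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.mode not in ("string", "geometry", "coordinate"):
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- constructors ---------------------------------------------------
    @classmethod
    def uniform_background(
        cls,
        n_positions: int,
        background: DistributionLike = "d",
        overrides: Optional[Dict[int, DistributionLike]] = None,
        first_resid: int = 1,
        **kwargs,
    ) -> "GeneratorSpec":
        """A background distribution everywhere, with per-residue overrides.

        ``overrides`` keys are author residue numbers.  The default pure-d
        background models a beta-strand core; loop-like positions are
        expressed as mixture overrides.
        """
        targets = np.tile(distribution(background), (n_positions, 1))
        for resid, dist in (overrides or {}).items():
            idx = resid - first_resid
            if not 0 <= idx < n_positions:
                raise ValueError(f"override residue {resid} outside range")
            targets[idx] = distribution(dist)
        return cls(targets=targets, first_resid=first_resid, **kwargs)

    @classmethod
    def from_letters(cls, letters: str, first_resid: int = 1, **kwargs) -> "GeneratorSpec":
        """One pure distribution per position, given as a PB string."""
        targets = np.stack([distribution(ch) for ch in letters])
        return cls(targets=targets, first_resid=first_resid, **kwargs)

    # -- derived --------------------------------------------------------
    @property
    def n_positions(self) -> int:
        return self.targets.shape[0]

    @property
    def resids(self) -> np.ndarray:
        return np.arange(self.first_resid, self.first_resid + self.n_positions)

    def analytic_neq(self) -> pd.Series:
        """Exact Neq of every target distribution (the recovery truth)."""
        values = np.empty(self.n_positions)
        for i, row in enumerate(self.targets):
            nz = row[row > 0]
            values[i] = np.exp(-np.sum(nz * np.log(nz)))
        return pd.Series(values, index=self.resids, name="neq")

    def segments(self) -> list:
        """Maximal runs of positions sharing one target distribution."""
        runs = []
        start = 0
        for i in range(1, self.n_positions):
            if not np.array_equal(self.targets[i], self.targets[start]):
                runs.append((start, i))
                start = i
        runs.append((start, self.n_positions))
        return runs


def _rng_for(spec: GeneratorSpec, replicate: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(
        spec.seed if replicate is None else spec.seed + replicate
    )


def generate_string_mode(
    spec: GeneratorSpec, replicate: Optional[int] = None
) -> PBEnsemble:
    """Draw letters i.i.d. from each position's target distribution."""
    rng = _rng_for(spec, replicate)
    letters = np.empty((spec.n_frames, spec.n_positions), dtype="U1")
    letter_arr = np.array(PB_LETTERS, dtype="U1")
    for j in range(spec.n_positions):
        draws = rng.choice(16, size=spec.n_frames, p=spec.targets[j])
        letters[:, j] = letter_arr[draws]
    return PBEnsemble(letters=letters, resids=spec.resids)


def _draw_segment_labels(
    spec: GeneratorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame letters, constant within each homogeneous segment."""
    labels = np.empty((spec.n_frames, spec.n_positions), dtype=int)
    for start, stop in spec.segments():
        draws = rng.choice(16, size=spec.n_frames, p=spec.targets[start])
        labels[:, start:stop] = draws[:, None]
    return labels


def generate_geometry_mode(
    spec: GeneratorSpec,
    alphabet: Optional[PBAlphabet] = None,
    replicate: Optional[int] = None,
) -> Tuple[DihedralSeries, PBEnsemble]:
    """Realise drawn letters as central-residue dihedrals plus noise.

    Returns the dihedral series and the generating letters (the ground
    truth for round-trip assignment checks).  phi of the first residue and
    psi of the last are NaN, as for a real chain.
    """
    alphabet = alphabet or PBAlphabet.default()
    rng = _rng_for(spec, replicate)
    labels = _draw_segment_labels(spec, rng)
    central = alphabet.reference_angles[:, 3:5]  # (16, 2): phi, psi
    phi = central[labels, 0]
    psi = central[labels, 1]
    if spec.sigma > 0:
        phi = wrap_degrees(phi + rng.normal(0.0, spec.sigma, phi.shape))
        psi = wrap_degrees(psi + rng.normal(0.0, spec.sigma, psi.shape))
    phi[:, 0] = np.nan
    psi[:, -1] = np.nan
    series = DihedralSeries(phi=phi, psi=psi, resids=spec.resids)
    letter_arr = np.array(PB_LETTERS, dtype="U1")
    return series, PBEnsemble(letters=letter_arr[labels], resids=spec.resids)


def generate_coordinate_mode(
    spec: GeneratorSpec,
    alphabet: Optional[PBAlphabet] = None,
    replicate: Optional[int] = None,
) -> Tuple[Ensemble, DihedralSeries, PBEnsemble]:
    """Geometry mode plus NeRF backbone building (N/CA/C, ideal geometry).

    Returns the coordinate ensemble together with the generating dihedrals
    and letters.  Write the ensemble with
    :func:`pbflex.io.write_ensemble` to obtain a multi-model PDB.
    """
    series, truth = generate_geometry_mode(spec, alphabet=alphabet, replicate=replicate)
    n_res = spec.n_positions
    coords = np.empty((spec.n_frames, n_res * 3, 3))
    for f in range(spec.n_frames):
        coords[f] = build_backbone(series.phi[f], series.psi[f]).reshape(-1, 3)
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * (n_res * 3),
            "resid": np.repeat(spec.resids, 3),
            "resname": ["ALA"] * (n_res * 3),
            "name": ["N", "CA", "C"] * n_res,
            "b_factor": np.zeros(n_res * 3),
        }
    )
    return Ensemble(coords, atoms), series, truth


def generate(spec: GeneratorSpec, replicate: Optional[int] = None):
    """Dispatch on ``spec.mode``."""
    if spec.mode == "string":
        return generate_string_mode(spec, replicate=replicate)
    if spec.mode == "geometry":
        return generate_geometry_mode(spec, replicate=replicate)
    return generate_coordinate_mode(spec, replicate=replicate)


def generate_replicates(spec: GeneratorSpec) -> list:
    """All replicates of a system (seed + replicate-index derivation)."""
    return [generate(spec, replicate=r) for r in range(spec.n_replicates)]


def inject_variant_effect(
    base: GeneratorSpec,
    site: int,
    distant: int,
    effect: DistributionLike,
) -> Tuple[GeneratorSpec, GeneratorSpec]:
    """Build the canonical long-range fixture: (WT spec, variant spec).

    The two specs are identical except that the *distant* position's
    distribution is replaced by ``effect``; the mutation *site* itself is
    untouched, emulating the "site stable, distant loop divergent"
    pattern of leg-domain variants.
    """
    for name, resid in (("site", site), ("distant", distant)):
        if not (base.first_resid <= resid < base.first_resid + base.n_positions):
            raise ValueError(f"{name} position {resid} outside residue range")
    targets = base.targets.copy()
    targets[distant - base.first_resid] = distribution(effect)
    return base, replace(base, targets=targets)


def expected_delta_pb(
    wt: GeneratorSpec, variant: GeneratorSpec
) -> pd.Series:
    """Analytic per-position dPB between two specs' target distributions."""
    if wt.n_positions != variant.n_positions or wt.first_resid != variant.first_resid:
        raise ValueError("specs must share a residue range")
    values = np.abs(wt.targets - variant.targets).sum(axis=1)
    return pd.Series(values, index=wt.resids, name="delta_pb")
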