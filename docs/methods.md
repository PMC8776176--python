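# Methods

## The Protein Blocks model

Protein Blocks (PBs) are a structural alphabet of 16 local-backbone
prototypes, labelled `a`–`p`, obtained originally by unsupervised training
on a non-redundant structure databank (de Brevern, Etchebest & Hazout,
2000). Each block is an 8-vector of reference dihedrals covering five
consecutive residues,

    (ψᵢ₋₂, φᵢ₋₁, ψᵢ₋₁, φᵢ, ψᵢ, φᵢ₊₁, ψᵢ₊₁, φᵢ₊₂),

with the assignment attributed to the central residue *i*. Block `m`
approximates the α-helix core and `d` the central β-strand; `a`–`c` are
strand N-caps, `e`–`f` strand C-caps, `k`–`l` helix N-caps, `n`–`p` helix
C-caps, and `a`–`j` cover coil. The reference table ships as
`src/pbflex/data/pb_reference_angles.tsv` (provenance in its header); it is
the package's single external constant.

**Assignment.** A residue's block is the arg-min over the 16 prototypes of
the unweighted angular RMSD of its window, √(⅛ Σⱼ wrap(θⱼ − refⱼ)²), with
wrap the minimal signed difference on (−180°, 180°] — the historical
convention for PB assignment. Ties (measure-zero on real data) break
alphabetically so assignment is deterministic; the dissimilarity is
pluggable for testing. Positions whose window is incomplete — the first two
and last two residues of the chain, or any window containing an undefined
dihedral — are marked `Z`. `Z` frames are dropped from a position's
frequency denominator, never counted as a 17th category; this package fixes
two excluded positions per terminus (the window geometry) and documents
that choice. Assignment is frame-independent: permuting frames permutes
output rows identically.

## Per-position statistics

With f_x the frequency of block *x* at a position over its non-`Z` frames:

* **Neq** = exp(−Σ f_x ln f_x), the exponential of the Shannon entropy
  (natural log, 0·ln 0 = 0), in [1, 16]. It reads as the number of blocks
  "effectively" sampled at the position.
* **Flexibility classes** follow the Neq scaling used for disorder
  analysis: Neq > 8 disordered; 6 < Neq ≤ 8 highly flexible; 3 ≤ Neq ≤ 6
  flexible (inherent flexibility sits "around 4", which is not a sharp
  boundary — the [3, 6] band is this package's explicit choice); Neq < 3
  rigid.
* **ΔNeq** = |Neq_A − Neq_B| and **ΔPB** = Σ_x |f_x^A − f_x^B| ∈ [0, 2]
  contrast two systems position by position, on the positions assignable in
  both. ΔPB is an L1 distance (symmetric, triangle inequality); identical
  profiles give 0, disjoint support gives 2. The per-letter difference
  vector is returned alongside so single-block statements ("an 80%
  difference for block h") can be read off.
* Positions with fewer than `min_count` (default 10) contributing frames
  are flagged low-confidence; empty positions (all `Z`) carry NaN Neq and
  are excluded downstream.

## Comparison pipeline and the long-range call

Two systems are compared by (i) Pearson correlation of their Neq and RMSF
tracks on shared positions (undefined for constant tracks, reported as
NaN), (ii) a divergence summary flagging positions with ΔPB strictly above
a threshold — default 1.0, the working definition of a significant local
change — annotated against the domain/loop registry, and (iii) a long-range
assessment: each flagged position is *local* within ± `window` residues of
the mutation site (default 5; "distant" has no canonical numerical
definition, so the window is an explicit, configurable choice) or *distant*
otherwise, and the headline `long_range` boolean is true when some distant
position is flagged while the site's own ΔPB stays below the
local-stability bound (default 0.2, bracketing the observed
stable-site values of ~0.02–0.07). A threshold at or above ΔPB's maximum
of 2 flags exactly the totally-disjoint positions, keeping the upper bound
reachable under strict comparison. All comparison measures are symmetric
in the two systems, and reports embed a hash of their configuration.

Replicate runs, when supplied, are pooled frame-wise for the headline
statistics; per-replicate profiles and their pairwise Neq correlations are
available to check that replicates sample comparable flexibility before
pooling.

## Geometry

* **Dihedrals**: φᵢ = C(i−1)–N(i)–CA(i)–C(i), ψᵢ = N(i)–CA(i)–C(i)–N(i+1),
  IUPAC sign convention, degrees on (−180°, 180°]; φ of the first and ψ of
  the last residue are undefined (NaN). The torsion is computed in double
  precision with an arctan2 formulation; generic structure toolkits often
  evaluate it in float32 (~3·10⁻⁵ deg error), which would consume a third
  of the 10⁻⁴-degree round-trip budget the synthetic generator guarantees,
  so the float64 version is used and the toolkit implementation serves as
  an independent cross-check in the tests.
* **Superposition**: least-squares (Kabsch) fit via rotation alignment;
  RMSD after superposition.
* **RMSF**: Cα only. Each frame is superposed onto the ensemble-average
  structure with one Kabsch pass, the mean is recomputed once, and
  RMSF_i = √⟨‖xᵢ − ⟨xᵢ⟩‖²⟩ over frames. The fitting reference is
  configurable (`mean`, the default, or `first`) since MD packages differ;
  units are Å by default, nm on request — unit handling is explicit rather
  than assumed because published RMSF magnitudes are ambiguous across
  toolchains. A single-frame ensemble yields an all-zero track with a
  warning. A configurable number of leading frames can be discarded before
  all statistics (equilibration burn-in; default 0 for synthetic data).
* **B-factor equivalent**: B = (8π²/3)·RMSF², the standard isotropic
  crystallographic relation, used only for side-by-side comparison with
  file B-factor columns.
* **Contact persistence**: fraction of frames in which the minimum
  distance between two atom selections is at or below a cutoff (default
  3.0 Å, a typical ion-coordination distance; no canonical value exists,
  so it is configurable), reported overall and per partner residue.
* **Chain building (NeRF)**: backbone N/CA/C coordinates are grown
  atom-by-atom from internal coordinates with ideal Engh–Huber bond
  lengths/angles and planar trans peptide bonds (ω = 180°). Building from
  prescribed (φ, ψ) and recomputing dihedrals round-trips to < 10⁻⁴ deg
  (measured ~10⁻¹³); through PDB serialisation, coordinates round-trip to
  the format's 10⁻³ Å precision.

## Synthetic data: what it emulates and what it does not

The generator stands in for replicated MD production runs: each position
has a target categorical distribution over the 16 blocks; `n_replicates`
(default 11) independent streams derive from `seed + replicate index`;
frames model snapshots saved every 100 ps (metadata only). Defaults —
pure `d` background for a β-strand core, mixtures for loops, σ = 10° of
wrapped Gaussian dihedral noise — caricature the rigid immunoglobulin-fold
systems the analysis was designed around.

* **String mode** draws letters i.i.d. per frame and position. It is the
  exact-recovery surface: empirical frequencies converge to the targets
  (binomial rate), so analytic Neq and ΔPB are recovered within 2% at
  10⁴ frames in the tests.
* **Geometry mode** realises each drawn letter as its prototype's central
  (φ, ψ) plus wrapped Gaussian noise. Because adjacent windows share
  dihedrals, arbitrary per-position mixtures are not simultaneously
  realisable; letters are therefore drawn once per homogeneous segment
  (a maximal run of positions sharing a target) per frame, keeping windows
  locally consistent. Recovery is exact at σ = 0 for self-consistent
  letters (verified for `m` and `d`) in segment interiors, approximate at
  segment boundaries, and degrades gracefully with σ.
* **Coordinate mode** additionally builds backbone coordinates via NeRF
  and can emit a multi-model PDB.

What passing tests on synthetic data do **not** show about real MD: the
generator has no forcefield, solvent, thermodynamics, temporal
autocorrelation between frames, or coupling between sequence and
conformational preference. It reproduces exactly the categorical/angular
statistics the analysis consumes, so the tests validate the measurement
chain, not the physics upstream of it.

## Region registry

Named inclusive intervals in author (PDB) numbering: the Thigh
(452–602), Calf-1 (603–743) and Calf-2 (744–959) domains, all Calf-1 and
Calf-2 loops, and the two expertly modeled Calf-2 loops (763–775,
840–873). `region_length` always reports the arithmetic length
end − start + 1; where a published residue count disagrees with its own
interval (Thigh "216" vs 151; modeled loop 1 "11" vs 13), the interval is
stored as printed and the discrepancy is logged, not silently corrected.
An alternative published Calf-2 end (952) exists; the registry follows
744–959. Flagged positions are annotated with the narrowest covering loop,
falling back to "`<domain>` inter-loop".

## Numerical choices and degenerate inputs

* Angles everywhere on (−180°, 180°], differences via minimal signed wrap.
* Frequency rows must sum to 1 within 10⁻⁶; Neq input validation rejects
  anything worse. Neq is compared against an independently coded entropy
  oracle to 10⁻¹² in the tests.
* Kabsch requires ≥ 3 points and equal counts; RMSD of congruent sets is
  zero to ~10⁻¹⁵ (tested at 10⁻⁹).
* Ensembles require ≥ 1 frame, identical atom tables across frames
  (violations name the first offending MODEL), finite coordinates; altloc
  "first" is kept and insertion codes are rejected.
* PB assignment requires ≥ 5 residues; chunked evaluation (256 frames per
  block) bounds memory for large ensembles.
* All TSV/CSV/JSON outputs use fixed float formatting, so identical
  configurations reproduce byte-identical files.

## Problem sizes in tests

The test and acceptance workloads use 10⁴-frame string-mode ensembles for
statistical recovery, 500-frame coordinate ensembles for RMSF statistics,
and 2000–5000-frame fixtures for the end-to-end comparison — sizes at which
the binomial/χ sampling error sits comfortably inside the asserted
tolerances while the whole suite runs in seconds.

## Known limitations

* Single-chain analysis only; no multi-chain assemblies, no PBC
  unwrapping, no mass-weighting, no solvent handling.
* No probabilistic smoothing of assignments and no alternative structural
  alphabets; no significance testing of ΔPB and no alternative divergences
  (Jensen–Shannon etc.).
* Binary trajectory support (XTC/DCD + PDB topology) is a thin optional
  adapter; multi-model PDB is the canonical, fully tested path.
* The long-range call is divergence geography, not mechanism: it does not
  infer allosteric pathways.
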