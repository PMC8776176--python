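"""System-vs-system comparison: correlations, divergence, long-range flags.

A "system" is one simulated construct (e.g. the wild-type Calf-1 + Calf-2
assembly, or a missense variant of it) reduced to its PB profile and
flexibility tracks.  Comparing two systems position by position yields
dNeq and dPB tracks; positions with dPB above a threshold (default 1, the
working definition of a significant local change) are flagged and mapped
onto the domain/loop registry.  A "long-range effect" is called when some
flagged position lies outside a local window around the mutation site
while the site itself stays locally stable (low dPB) — the signature of
allosteric compensation seen for leg-domain variants.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import FlexProfile, PBProfile, delta_neq, delta_pb_profile
from .regions import RegionRegistry


@dataclass
class SystemRun:
    """One system's profiles, with provenance for reproducibility."""

    label: str
    pb_profile: PBProfile
    flex: FlexProfile
    replicate_profiles: Optional[list] = None
    provenance: dict = field(default_factory=dict)


@dataclass
class ComparisonRecord:
    """Per-position dNeq / dPB between two labelled systems."""

    label_a: str
    label_b: str
    table: pd.DataFrame  # index residue; delta_neq, delta_pb, d_<letter>...

    @property
    def delta_pb(self) -> pd.Series:
        return self.table["delta_pb"]

    @property
    def delta_neq(self) -> pd.Series:
        return self.table["delta_neq"]


def compare_profiles(a: SystemRun, b: SystemRun) -> ComparisonRecord:
    """dNeq and dPB tracks on the positions assignable in both systems."""
    dpb = delta_pb_profile(a.pb_profile, b.pb_profile)
    dneq = delta_neq(a.flex, b.flex)
    table = dpb.join(dneq, how="inner")
    table = table[["delta_neq"] + [c for c in dpb.columns]]
    return ComparisonRecord(label_a=a.label, label_b=b.label, table=table)


def profile_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson r between two per-residue tracks on their shared positions.

    Requires at least 3 shared finite positions; a constant track makes
    the correlation undefined (NaN, with a warning).
    """
    shared = a.index.intersection(b.index)
    x = a[shared].to_numpy(dtype=float)
    y = b[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared positions for a correlation")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined for a constant track")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class DivergenceSummary:
    """Positions with dPB above threshold, with region annotations."""

    threshold: float
    flagged: pd.DataFrame  # residue-indexed: delta_pb, delta_neq, region
    fraction: float  # flagged / assignable-in-both
    argmax_delta_pb: int
    argmax_delta_neq: int


def divergence_summary(
    record: ComparisonRecord,
    threshold: float = 1.0,
    registry: Optional[RegionRegistry] = None,
) -> DivergenceSummary:
    """Flag positions whose dPB exceeds ``threshold`` and annotate regions.

    Flagging is strict (dPB > threshold); a threshold at or above the
    metric's maximum of 2 flags exactly the totally disjoint positions
    (dPB = 2), so the upper bound remains reachable.
    """
    if len(record.table) == 0:
        raise ValueError("empty comparison record")
    registry = registry or RegionRegistry.default()
    effective = min(threshold, 2.0 - 1e-9)
    mask = record.delta_pb > effective
    flagged = record.table.loc[mask, ["delta_pb", "delta_neq"]].copy()
    flagged["region"] = [registry.annotate(int(r)) for r in flagged.index]
    return DivergenceSummary(
        threshold=threshold,
        flagged=flagged,
        fraction=float(mask.mean()),
        argmax_delta_pb=int(record.delta_pb.idxmax()),
        argmax_delta_neq=int(record.delta_neq.idxmax()),
    )


@dataclass
class LongRangeAssessment:
    """Local/distant split of flagged positions and the headline call."""

    mutation_site: int
    window: int
    local_stability_bound: float
    site_delta_pb: float
    labels: pd.Series  # flagged residue -> "local" | "distant"
    long_range: bool


def long_range_flag(
    record: ComparisonRecord,
    summary: DivergenceSummary,
    mutation_site: int,
    window: int = 5,
    local_stability_bound: float = 0.2,
) -> LongRangeAssessment:
    """Call a long-range (allosteric) effect from a divergence summary.

    Each flagged position is ``local`` within +/- ``window`` residues of
    the mutation site, else ``distant``.  The headline boolean is true
    when a distant position is flagged while the site's own dPB stays
    below ``local_stability_bound`` — i.e. the local conformation at the
    mutation is conserved but remote positions diverge.
    """
    if mutation_site not in record.table.index:
        raise ValueError(
            f"mutation site {mutation_site} is not an assignable position "
            f"of the comparison"
        )
    site_dpb = float(record.delta_pb.loc[mutation_site])
    labels = pd.Series(
        [
            "local" if abs(int(r) - mutation_site) <= window else "distant"
            for r in summary.flagged.index
        ],
        index=summary.flagged.index,
        name="range",
        dtype=object,
    )
    long_range = bool(
        (labels == "distant").any() and site_dpb < local_stability_bound
    )
    return LongRangeAssessment(
        mutation_site=mutation_site,
        window=window,
        local_stability_bound=local_stability_bound,
        site_delta_pb=site_dpb,
        labels=labels,
        long_range=long_range,
    )


@dataclass
class ComparisonReport:
    """Everything the WT-vs-variant comparison produces."""

    record: ComparisonRecord
    summary: DivergenceSummary
    neq_correlation: float
    rmsf_correlation: Optional[float]
    assessment: Optional[LongRangeAssessment]
    config: dict
    config_hash: str

    def to_dict(self) -> dict:
        out = {
            "systems": [self.record.label_a, self.record.label_b],
            "config": self.config,
            "config_hash": self.config_hash,
            "neq_correlation": _json_float(self.neq_correlation),
            "rmsf_correlation": _json_float(self.rmsf_correlation),
            "threshold": self.summary.threshold,
            "fraction_flagged": self.summary.fraction,
            "argmax_delta_pb": self.summary.argmax_delta_pb,
            "argmax_delta_neq": self.summary.argmax_delta_neq,
            "flagged_positions": [
                {
                    "residue": int(res),
                    "delta_pb": round(float(row["delta_pb"]), 6),
                    "delta_neq": round(float(row["delta_neq"]), 6),
                    "region": row["region"],
                }
                for res, row in self.summary.flagged.iterrows()
            ],
        }
        if self.assessment is not None:
            out["mutation_site"] = self.assessment.mutation_site
            out["site_delta_pb"] = round(self.assessment.site_delta_pb, 6)
            out["long_range"] = self.assessment.long_range
            out["range_labels"] = {
                str(int(r)): v for r, v in self.assessment.labels.items()
            }
        return out


def _json_float(x):
    if x is None:
        return None
    x = float(x)
    return None if not np.isfinite(x) else round(x, 6)


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def compare_systems(
    a: SystemRun,
    b: SystemRun,
    mutation_site: Optional[int] = None,
    threshold: float = 1.0,
    window: int = 5,
    local_stability_bound: float = 0.2,
    registry: Optional[RegionRegistry] = None,
) -> ComparisonReport:
    """Full comparison of two systems.

    Computes the dNeq/dPB record, Pearson correlations of the Neq (and,
    when available, RMSF) tracks, the divergence summary at ``threshold``
    and — when ``mutation_site`` is given — the long-range assessment.
    All measures are symmetric in the two systems.
    """
    record = compare_profiles(a, b)
    summary = divergence_summary(record, threshold=threshold, registry=registry)
    neq_r = profile_correlation(a.flex.neq, b.flex.neq)
    rmsf_r = None
    if a.flex.rmsf is not None and b.flex.rmsf is not None:
        rmsf_r = profile_correlation(a.flex.rmsf, b.flex.rmsf)
    assessment = None
    if mutation_site is not None:
        assessment = long_range_flag(
            record, summary, mutation_site,
            window=window, local_stability_bound=local_stability_bound,
        )
    config = {
        "threshold": threshold,
        "window": window,
        "local_stability_bound": local_stability_bound,
        "mutation_site": mutation_site,
    }
    return ComparisonReport(
        record=record,
        summary=summary,
        neq_correlation=neq_r,
        rmsf_correlation=rmsf_r,
        assessment=assessment,
        config=config,
        config_hash=_hash_config(config),
    )


def replicate_neq_correlations(profiles: list) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-replicate Neq tracks.

    Used to check that independent replicate runs sample comparable
    flexibility before pooling them.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicate profiles")
    tracks = [p.neq_track() for p in profiles]
    rows = []
    for (i, ti), (j, tj) in combinations(enumerate(tracks), 2):
        rows.append((i, j, profile_correlation(ti, tj)))
    return pd.DataFrame(rows, columns=["replicate_a", "replicate_b", "pearson_r"])
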