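"""Named residue-interval registry for the integrin alpha-IIb leg domains.

The registry holds the domain and loop coordinates of the alpha-IIb lower
leg (Thigh, Calf-1, Calf-2 — immunoglobulin-fold domains; author/PDB
numbering, inclusive intervals).  Positions flagged by the comparison
pipeline are annotated against these intervals so that divergence can be
localised to a specific loop.

Note on published coordinates: the printed residue count for Thigh
(216) disagrees with the printed interval 452-602 (151 residues), and the
"11 residue" first modeled Calf-2 loop spans 13 positions (763-775).
The registry stores the intervals as printed and always reports the
arithmetic length ``end - start + 1``; the discrepancies are logged at
registry construction, not silently corrected.  An alternative Calf-2
bound (744-952) appears in the source literature; the registry uses
744-959.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """An inclusive residue interval in author (PDB) numbering."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region {self.name!r}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, resid: int) -> bool:
        return self.start <= resid <= self.end


# Domain and loop coordinates of the alpha-IIb leg (author numbering).
_DOMAINS = {
    "Thigh": (452, 602),
    "Calf-1": (603, 743),
    "Calf-2": (744, 959),
}

_CALF1_LOOPS = {
    "Calf-1 loop 1": (603, 612),
    "Calf-1 loop 2": (620, 629),
    "Calf-1 loop 3": (639, 646),
    "Calf-1 loop 4": (653, 657),
    "Calf-1 loop 5": (663, 673),
    "Calf-1 loop 6": (678, 683),
    "Calf-1 loop 7": (691, 696),
    "Calf-1 loop 8": (707, 715),
    "Calf-1 loop 9": (724, 735),
}

_CALF2_LOOPS = {
    "Calf-2 loop 1": (742, 747),
    "Calf-2 loop 2": (755, 757),
    "Calf-2 loop 3": (761, 776),
    "Calf-2 loop 4": (788, 795),
    "Calf-2 loop 5": (805, 812),
    "Calf-2 loop 6": (821, 824),
    "Calf-2 loop 7": (829, 884),
    "Calf-2 loop 8": (893, 897),
    "Calf-2 loop 9": (909, 921),
    "Calf-2 loop 10": (931, 945),
}

_MODELED_LOOPS = {
    "Calf-2 modeled loop 1": (763, 775),
    "Calf-2 modeled loop 2": (840, 873),
}

# Residue counts printed alongside the intervals in the source coordinates;
# mismatches with interval arithmetic are reported, never adopted.
_PRINTED_LENGTHS = {
    "Thigh": 216,
    "Calf-1": 141,
    "Calf-2": 216,
    "Calf-2 modeled loop 1": 11,
    "Calf-2 modeled loop 2": 34,
}


@dataclass
class RegionRegistry:
    """Lookup table of named residue intervals.

    The default registry (``RegionRegistry.default()``) carries the
    Thigh/Calf-1/Calf-2 domains, every Calf-1 and Calf-2 loop, and the two
    expertly modeled Calf-2 loops.
    """

    regions: Dict[str, Region] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "RegionRegistry":
        reg = cls()
        for table in (_DOMAINS, _CALF1_LOOPS, _CALF2_LOOPS, _MODELED_LOOPS):
            for name, (start, end) in table.items():
                reg.add(name, start, end)
        for name, printed in _PRINTED_LENGTHS.items():
            actual = reg.regions[name].length
            if actual != printed:
                logger.warning(
                    "region %r: printed residue count %d disagrees with "
                    "interval %d-%d (arithmetic length %d); reporting %d",
                    name, printed, reg.regions[name].start,
                    reg.regions[name].end, actual, actual,
                )
        return reg

    def add(self, name: str, start: int, end: int) -> None:
        self.regions[name] = Region(name, start, end)

    def __getitem__(self, name: str) -> Region:
        try:
            return self.regions[name]
        except KeyError:
            valid = ", ".join(sorted(self.regions))
            raise KeyError(
                f"unknown region {name!r}; valid names: {valid}"
            ) from None

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions.values())

    def __len__(self) -> int:
        return len(self.regions)

    def region_length(self, name: str) -> int:
        """Arithmetic length (end - start + 1) of the named interval."""
        return self[name].length

    def lookup(self, name: str) -> Tuple[Tuple[int, int], int]:
        """Return ((start, end), length) for a named region."""
        r = self[name]
        return (r.start, r.end), r.length

    def annotate(self, resid: int) -> str:
        """Most specific region name covering a residue.

        Loops take precedence over domains; residues inside a domain but
        outside every loop are labelled ``"<domain> inter-loop"``; residues
        outside all regions are ``"inter-loop"``.
        """
        loops = [
            r for r in self
            if resid in r and r.name not in _DOMAINS
        ]
        if loops:
            # narrowest covering loop wins
            return min(loops, key=lambda r: r.length).name
        for r in self:
            if resid in r and r.name in _DOMAINS:
                return f"{r.name} inter-loop"
        return "inter-loop"

    def to_frame(self) -> pd.DataFrame:
        """BED-like table (name, start, end, length), inclusive coordinates."""
        return pd.DataFrame(
            [(r.name, r.start, r.end, r.length) for r in self],
            columns=["name", "start", "end", "length"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
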