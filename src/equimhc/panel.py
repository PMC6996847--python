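"""Microsatellite locus panels.

A panel is the ordered coordinate system for everything downstream: loci are
sorted along the chromosome by ``map_index``, and recombination breakpoints are
reported as intervals named by the flanking locus pair (no physical positions
are used). The default panel is the 11-marker intra-MHC panel on equine
chromosome 20, spanning the class I, class III and class II subregions in that
map order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

MHC_CLASSES = ("I", "II", "III")


@dataclass(frozen=True)
class LocusDef:
    """A single microsatellite locus.

    Parameters
    ----------
    name : str
        Marker name, unique within a panel.
    mhc_class : str
        MHC subregion the marker sits in: ``"I"``, ``"II"`` or ``"III"``.
    map_index : int
        Position rank along the chromosome (0-based, strictly increasing
        within a panel).
    repeat_unit : int
        Repeat-unit length in bp. Alleles are fragment sizes, and stepwise
        insertion/deletion events shift an allele by integer multiples of
        this unit. Default 2 (dinucleotide).
    size_range : tuple of (int, int), optional
        Inclusive plausible fragment-size range in bp; used by the simulator
        to place allele lattices and by event calling to sanity-check shifts.
    """

    name: str
    mhc_class: str
    map_index: int
    repeat_unit: int = 2
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if self.mhc_class not in MHC_CLASSES:
            raise ValueError(f"mhc_class must be one of {MHC_CLASSES}, got {self.mhc_class!r}")
        if self.map_index < 0:
            raise ValueError("map_index must be non-negative")
        if self.repeat_unit < 1:
            raise ValueError("repeat_unit must be >= 1")
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range must be (min, max) with min <= max")


@dataclass(frozen=True)
class LocusPanel:
    """An ordered collection of loci forming the haplotype coordinate system."""

    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        loci = tuple(self.loci)
        object.__setattr__(self, "loci", loci)
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique within a panel")
        idx = [l.map_index for l in loci]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("map_index must be strictly increasing in panel order")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[LocusDef]:
        return iter(self.loci)

    def __getitem__(self, i: int) -> LocusDef:
        return self.loci[i]

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.loci]

    def index(self, name: str) -> int:
        for i, l in enumerate(self.loci):
            if l.name == name:
                return i
        raise KeyError(f"locus {name!r} not in panel")

    def locus(self, name: str) -> LocusDef:
        return self.loci[self.index(name)]

    def intervals(self) -> list[tuple[str, str]]:
        """Map-adjacent locus pairs — candidate crossover intervals."""
        return [(a.name, b.name) for a, b in zip(self.loci, self.loci[1:])]

    def to_json(self, path) -> None:
        payload = [
            {
                "name": l.name,
                "mhc_class": l.mhc_class,
                "map_index": l.map_index,
                "repeat_unit": l.repeat_unit,
                "size_range": list(l.size_range) if l.size_range else None,
            }
            for l in self.loci
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LocusPanel":
        with open(path) as fh:
            payload = json.load(fh)
        loci = tuple(
            LocusDef(
                name=e["name"],
                mhc_class=e["mhc_class"],
                map_index=int(e["map_index"]),
                repeat_unit=int(e.get("repeat_unit", 2)),
                size_range=tuple(e["size_range"]) if e.get("size_range") else None,
            )
            for e in payload
        )
        return cls(loci)


#: Default 11-marker intra-MHC panel in chromosome map order. Class I at one
#: end, class III in the middle, class II at the other end. The internal order
#: of the three class I markers is not fully constrained by published maps and
#: is configurable by building a custom panel.
_DEFAULT = (
    ("COR110", "I", (216, 262)),
    ("UMN-JH38", "I", (143, 161)),
    ("TAMU30593", "I", (108, 152)),
    ("ABGe9019", "III", (162, 204)),
    ("UMNe65", "III", (126, 168)),
    ("ABGe9030", "II", (178, 216)),
    ("TKY3324", "II", (244, 288)),
    ("COR112", "II", (228, 270)),
    ("COR113", "II", (182, 230)),
    ("UM011", "II", (154, 200)),
    ("COR114", "II", (252, 296)),
)


def default_panel() -> LocusPanel:
    """The 11-locus equine MHC microsatellite panel in map order."""
    return LocusPanel(
        tuple(
            LocusDef(name=n, mhc_class=c, map_index=i, repeat_unit=2, size_range=r)
            for i, (n, c, r) in enumerate(_DEFAULT)
        )
    )
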