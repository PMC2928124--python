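"""Core domain types: single-pass membrane proteins and organelle sets.

Coordinates are 1-based inclusive on the N->C sequence in all public
interfaces and file formats. Topology follows the standard single-pass
classes: type II proteins have their N terminus in the cytosol; types I and
III have it in the exoplasmic space, so their TMDs must be read C->N to run
from the cytosolic to the exoplasmic side of the bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scales import AMINO_ACIDS

__all__ = ["BitopicProtein", "OrganelleDataset", "TOPOLOGIES"]

TOPOLOGIES = ("I", "II", "III")

_STANDARD = set(AMINO_ACIDS)


@dataclass(frozen=True)
class BitopicProtein:
    """One single-pass (bitopic) membrane protein.

    Attributes
    ----------
    id
        Unique record identifier.
    sequence
        Amino-acid string, N->C, 20-letter alphabet only. Records containing
        nonstandard letters (B, Z, X, U, O, ...) are rejected at construction:
        silently substituting property values for them would bias positional
        profiles.
    topology
        ``"I"``, ``"II"`` or ``"III"``.
    organelle
        Organelle-of-residence label (e.g. ``"ER"``, ``"Golgi"``, ``"PM"``).
    guide_tmd
        Approximate TMD interval, 1-based inclusive, used as the starting
        guide for hydrophobicity edge scanning. Must be at least 10 residues.
    species_tag
        Optional provenance tag (species of origin for ortholog sets).
    """

    id: str
    sequence: str
    topology: str
    organelle: str
    guide_tmd: tuple[int, int]
    species_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        bad = sorted(set(self.sequence) - _STANDARD)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: nonstandard residue(s) {''.join(bad)!r} in sequence"
            )
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"protein {self.id!r}: topology must be one of {TOPOLOGIES}, got {self.topology!r}"
            )
        start, end = self.guide_tmd
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"protein {self.id!r}: guide interval ({start}, {end}) out of bounds "
                f"for sequence of length {len(self.sequence)}"
            )
        if end - start + 1 < 10:
            raise ValueError(
                f"protein {self.id!r}: guide interval ({start}, {end}) shorter than 10 residues"
            )

    def guide_region(self, flank: int = 0) -> str:
        """Return the guide-interval substring, extended by ``flank`` residues
        on each side (clamped at the sequence ends)."""
        start, end = self.guide_tmd
        lo = max(1, start - flank)
        hi = min(len(self.sequence), end + flank)
        return self.sequence[lo - 1 : hi]


@dataclass
class OrganelleDataset:
    """A set of bitopic proteins sharing one organelle-of-residence label."""

    organelle: str
    proteins: list[BitopicProtein] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.proteins]
        if len(ids) != len(set(ids)):
            seen, dupes = set(), set()
            for i in ids:
                (dupes if i in seen else seen).add(i)
            raise ValueError(f"duplicate protein ids in dataset: {sorted(dupes)}")
        for p in self.proteins:
            if p.organelle != self.organelle:
                raise ValueError(
                    f"protein {p.id!r} labelled {p.organelle!r} in {self.organelle!r} dataset"
                )

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)
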