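"""Hydrophobic-core edge definition and bilayer orientation.

The central primitive is a hydrophobicity scan that refines an approximate
("guide") TMD interval into the edges of the hydrophobic core. Starting from
a guide edge indented 4 residues toward the TMD center, a 5-residue window
centered on the candidate position slides outward one residue at a time. The
core extends while the window mean stays at or below the scale's window
threshold *and* the candidate residue itself stays at or below the
individual-residue threshold (which only the charged residues D, E, K, R
exceed on the GES scale). The returned edge is the outermost passing
candidate; the scan also stops at the sequence ends, where windows are
truncated and the mean taken over the residues that exist.

Once both edges are known, every TMD is re-indexed so that position 1 is the
cytosolic edge of the hydrophobic core and increasing positions move toward
the exoplasmic side, regardless of topology: type II proteins are read N->C,
types I and III C->N. Cytosolic flank residues occupy positions <= 0 and the
exoplasmic flank positions > hydrophobic length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .proteins import BitopicProtein
from .scales import HydrophobicityScale

__all__ = [
    "NoHydrophobicCore",
    "TMDAnnotation",
    "AlignedTMD",
    "scan_edge",
    "annotate_tmd",
    "orient_cytosolic",
]


class NoHydrophobicCore(ValueError):
    """Raised when no candidate position passes the edge rule."""


@dataclass(frozen=True)
class TMDAnnotation:
    """Scanned hydrophobic-core edges of one protein, in sequence coordinates.

    ``cytosolic_edge`` and ``exoplasmic_edge`` are 1-based indices on the N->C
    sequence; for type II proteins the cytosolic edge is the N-terminal one,
    for types I and III the C-terminal one. ``hydrophobic_length`` counts the
    residues between the edges inclusive.
    """

    protein_id: str
    cytosolic_edge: int
    exoplasmic_edge: int
    hydrophobic_length: int
    scale_name: str

    def __post_init__(self) -> None:
        if self.hydrophobic_length != abs(self.exoplasmic_edge - self.cytosolic_edge) + 1:
            raise ValueError("hydrophobic_length inconsistent with edges")
        if self.hydrophobic_length < 1:
            raise ValueError("hydrophobic_length must be >= 1")


@dataclass(frozen=True)
class AlignedTMD:
    """A protein re-indexed onto the bilayer-oriented coordinate system.

    ``oriented_residues`` maps position -> residue where position 1 is the
    cytosolic-edge residue and positions increase toward the exoplasmic side;
    positions <= 0 are cytosolic flank and positions > ``hydrophobic_length``
    exoplasmic flank (populated only where the sequence extends that far).
    """

    protein_id: str
    oriented_residues: dict[int, str]
    hydrophobic_length: int

    def residue(self, position: int) -> str | None:
        return self.oriented_residues.get(position)

    def core_string(self) -> str:
        """The hydrophobic core read cytosol->exoplasm."""
        return "".join(self.oriented_residues[p] for p in range(1, self.hydrophobic_length + 1))

    def region_string(self, start: int, end: int) -> str:
        """Residues at oriented positions start..end inclusive, skipping
        positions that fall outside the sequence."""
        return "".join(
            self.oriented_residues[p]
            for p in range(start, end + 1)
            if p in self.oriented_residues
        )


def _window_mean(sequence: str, center: int, scale: HydrophobicityScale) -> float:
    """Mean scale value of the window centered on ``center`` (1-based),
    truncated at the sequence termini."""
    half = scale.window // 2
    lo = max(1, center - half)
    hi = min(len(sequence), center + half)
    vals = [scale[sequence[i - 1]] for i in range(lo, hi + 1)]
    return sum(vals) / len(vals)


_SIDE_ALIASES = {
    "cytosolic": "n",
    "start": "n",
    "n": "n",
    "exoplasmic": "c",
    "end": "c",
    "c": "c",
}


def scan_edge(
    sequence: str,
    guide_interval: tuple[int, int],
    side: str,
    scale: HydrophobicityScale,
) -> int:
    """Refine one guide edge into a hydrophobic-core edge.

    Parameters
    ----------
    sequence
        Full protein sequence, N->C.
    guide_interval
        Approximate TMD interval, 1-based inclusive.
    side
        ``"cytosolic"`` refines the N-terminal guide edge and
        ``"exoplasmic"`` the C-terminal one, under a type II reading of the
        sequence (N terminus cytosolic). For types I and III the caller swaps
        the labels afterwards; see :func:`annotate_tmd`.
    scale
        Hydrophobicity scale supplying window/residue thresholds.

    Returns
    -------
    int
        1-based index of the outermost candidate position for which the
        centered window mean is <= the window threshold and the candidate
        residue's value is <= the individual-residue threshold.

    Raises
    ------
    NoHydrophobicCore
        If even the indented starting candidate fails the rule.
    """
    start, end = guide_interval
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(f"guide interval ({start}, {end}) out of sequence bounds")
    if end - start + 1 < scale.indent + scale.window:
        raise ValueError(
            f"guide interval ({start}, {end}) shorter than indent + window "
            f"({scale.indent + scale.window}) residues"
        )
    which = _SIDE_ALIASES.get(side)
    if which is None:
        raise ValueError(f"side must be 'cytosolic' or 'exoplasmic', got {side!r}")
    if which == "n":
        candidate, step, limit = start + scale.indent, -1, 1
    else:
        candidate, step, limit = end - scale.indent, +1, len(sequence)

    def passes(c: int) -> bool:
        return (
            _window_mean(sequence, c, scale) <= scale.window_threshold
            and scale[sequence[c - 1]] <= scale.residue_threshold
        )

    if not passes(candidate):
        raise NoHydrophobicCore(
            f"no hydrophobic core: candidate {candidate} fails the edge rule "
            f"({scale.name} scale)"
        )
    while candidate != limit and passes(candidate + step):
        candidate += step
    return candidate


def annotate_tmd(protein: BitopicProtein, scale: HydrophobicityScale) -> TMDAnnotation:
    """Scan both edges of a protein's TMD and label them by bilayer side.

    Both sequence-terminal edges are refined with :func:`scan_edge`; the
    topology then decides which is cytosolic: the N-terminal edge for type II
    (N terminus in the cytosol), the C-terminal edge for types I and III.
    """
    n_edge = scan_edge(protein.sequence, protein.guide_tmd, "cytosolic", scale)
    c_edge = scan_edge(protein.sequence, protein.guide_tmd, "exoplasmic", scale)
    if protein.topology == "II":
        cyt, exo = n_edge, c_edge
    else:
        cyt, exo = c_edge, n_edge
    return TMDAnnotation(
        protein_id=protein.id,
        cytosolic_edge=cyt,
        exoplasmic_edge=exo,
        hydrophobic_length=abs(exo - cyt) + 1,
        scale_name=scale.name,
    )


def orient_cytosolic(
    protein: BitopicProtein, annotation: TMDAnnotation, flank: int = 10
) -> AlignedTMD:
    """Re-index a protein cytosol->exoplasm relative to its core edges.

    ``flank`` controls how many flank residues are captured on each side:
    cytosolic flank at positions ``-(flank - 1) .. 0`` and exoplasmic flank at
    positions ``L + 1 .. L + flank``, populated only where the sequence
    extends that far.
    """
    direction = 1 if protein.topology == "II" else -1
    length = annotation.hydrophobic_length
    residues: dict[int, str] = {}
    for position in range(1 - flank, length + flank + 1):
        index = annotation.cytosolic_edge + (position - 1) * direction
        if 1 <= index <= len(protein.sequence):
            residues[position] = protein.sequence[index - 1]
    return AlignedTMD(
        protein_id=protein.id,
        oriented_residues=residues,
        hydrophobic_length=length,
    )
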