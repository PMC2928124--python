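"""Leaflet asymmetry, helical size moments, and consensus TMDs.

The bilayer is treated as two leaflets: the *inner* leaflet spans oriented
positions 1..floor(L/2) of a TMD of hydrophobic length L (cytosolic half)
and the *outer* leaflet the remainder, with the midpoint residue of an
odd-length TMD assigned to the outer half. The leaflet-preference ratio of
a residue type is (outer − inner)/(outer + inner) half-normalized abundance:
+1 means exclusively outer, −1 exclusively inner, 0 no preference.

The size moment detects one-sided flattening of a helix (such as GXXXG
dimerization motifs): each residue contributes a planar vector of length
equal to its volume at an angle of n x 100 degrees (the per-residue twist of
an ideal alpha helix), vectors are summed over a 7-residue window (700
degrees, almost two turns) and the magnitude is reported at the window's
central residue. Only the magnitude is meaningful; the angular origin is
immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import FrequencyMatrix
from .scales import AMINO_ACIDS
from .tmd_edges import AlignedTMD

__all__ = [
    "LeafletPreference",
    "leaflet_preference",
    "size_moment_profile",
    "consensus_tmd",
]


@dataclass(frozen=True)
class LeafletPreference:
    """Per-residue outer-vs-inner leaflet enrichment.

    ``ratio`` holds the protein-averaged (outer − inner)/(outer + inner)
    abundance ratio in [−1, +1] (positive = outer-leaflet enriched), ``sem``
    its standard error over proteins, and ``n`` the number of proteins in
    which the residue occurred at all; residues never observed are NaN.
    """

    ratio: pd.Series
    sem: pd.Series
    n: pd.Series


def _half_abundances(aligned: AlignedTMD) -> tuple[dict[str, float], dict[str, float]]:
    length = aligned.hydrophobic_length
    split = length // 2
    inner = [aligned.oriented_residues[p] for p in range(1, split + 1)]
    outer = [aligned.oriented_residues[p] for p in range(split + 1, length + 1)]

    def normalize(residues):
        total = len(residues)
        out = {aa: 0.0 for aa in AMINO_ACIDS}
        for r in residues:
            out[r] += 1.0 / total
        return out

    return normalize(inner), normalize(outer)


def leaflet_preference(aligned_set: list[AlignedTMD]) -> LeafletPreference:
    """Per-residue leaflet-preference ratios, protein-averaged.

    For each protein the ratio (outer − inner)/(outer + inner) is computed
    from half-normalized abundances for every residue present in at least
    one half; the reported value is the mean of these per-protein ratios
    with its standard error over proteins. Residues absent from every
    protein's core are reported as missing (NaN).
    """
    if not aligned_set:
        raise ValueError("leaflet_preference requires a non-empty set")
    per_residue: dict[str, list[float]] = {aa: [] for aa in AMINO_ACIDS}
    for aligned in aligned_set:
        if aligned.hydrophobic_length < 2:
            raise ValueError(
                f"protein {aligned.protein_id!r}: hydrophobic length < 2, cannot split leaflets"
            )
        inner, outer = _half_abundances(aligned)
        for aa in AMINO_ACIDS:
            total = inner[aa] + outer[aa]
            if total > 0:
                per_residue[aa].append((outer[aa] - inner[aa]) / total)
    ratio, sem, n = {}, {}, {}
    for aa in AMINO_ACIDS:
        vals = per_residue[aa]
        n[aa] = len(vals)
        if vals:
            ratio[aa] = float(np.mean(vals))
            sem[aa] = (
                float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        else:
            ratio[aa] = np.nan
            sem[aa] = np.nan
    order = list(AMINO_ACIDS)
    return LeafletPreference(
        ratio=pd.Series(ratio)[order],
        sem=pd.Series(sem)[order],
        n=pd.Series(n)[order],
    )


def size_moment_profile(
    aligned: AlignedTMD,
    volume_table: dict[str, float],
    window: int = 7,
    angle_step: float = 100.0,
) -> pd.Series:
    """Helical size-moment magnitude at each fully covered window center.

    Returns a Series indexed by oriented position of the window's central
    residue; positions whose window extends past the available residues are
    skipped. Units follow the volume table (cubic Angstroms).
    """
    half = window // 2
    positions = sorted(aligned.oriented_residues)
    out: dict[int, float] = {}
    step = np.deg2rad(angle_step)
    for center in positions:
        span = range(center - half, center + half + 1)
        if any(p not in aligned.oriented_residues for p in span):
            continue
        vec = complex(0.0, 0.0)
        for k, p in enumerate(span):
            volume = volume_table[aligned.oriented_residues[p]]
            vec += volume * np.exp(1j * k * step)
        out[center] = abs(vec)
    return pd.Series(out)


def consensus_tmd(matrix: FrequencyMatrix, positions) -> str:
    """Most-abundant residue at each requested position, as a string.

    Ties are broken lexicographically (the residue axis is laid out in
    alphabetical one-letter order).
    """
    residues = []
    for pos in positions:
        if pos not in matrix.abundance.index or matrix.counts[pos] == 0:
            raise ValueError(f"position {pos} has no contributing proteins")
        residues.append(matrix.abundance.loc[pos].idxmax())
    return "".join(residues)
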