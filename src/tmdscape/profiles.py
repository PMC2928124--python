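"""Positional analytics over cytosol-aligned TMD sets.

All statistics here are computed on the oriented coordinate system of
:class:`~tmdscape.tmd_edges.AlignedTMD` (position 1 = cytosolic edge of the
hydrophobic core, increasing toward the exoplasmic side). Flank positions
are included where sequence exists, so per-position sample sizes vary; the
``n`` track records how many proteins contributed at each position.

Per-position p-values are raw two-sample t tests, reported without
multiple-testing correction across positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scales import AMINO_ACIDS
from .tmd_edges import AlignedTMD, TMDAnnotation

__all__ = [
    "FrequencyMatrix",
    "PositionalProfile",
    "LengthDistribution",
    "frequency_matrix",
    "positional_profile",
    "compare_profiles",
    "compare_lengths",
    "length_distribution",
]


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position residue abundances, normalized to one at each position.

    ``abundance`` is a DataFrame indexed by oriented position with one column
    per residue (fixed order ``ACDEFGHIKLMNPQRSTVWY``); ``counts`` gives the
    number of proteins contributing at each position.
    """

    abundance: pd.DataFrame
    counts: pd.Series

    @property
    def positions(self) -> list[int]:
        return list(self.abundance.index)


@dataclass(frozen=True)
class PositionalProfile:
    """Mean property value (hydropathy in kcal/mol, or volume in cubic
    Angstroms) per oriented position, with SEM and per-position n."""

    mean: pd.Series
    sem: pd.Series
    n: pd.Series

    @property
    def positions(self) -> list[int]:
        return list(self.mean.index)


@dataclass(frozen=True)
class LengthDistribution:
    """Exact histogram of hydrophobic lengths for one protein set."""

    histogram: dict[int, int]
    mean: float
    n: int

    def values(self) -> np.ndarray:
        """Expand the histogram back into one length per protein."""
        return np.array(
            [length for length, count in sorted(self.histogram.items()) for _ in range(count)]
        )


def _position_range(aligned_set: list[AlignedTMD]) -> range:
    lo = min(min(a.oriented_residues) for a in aligned_set)
    hi = max(max(a.oriented_residues) for a in aligned_set)
    return range(lo, hi + 1)


def frequency_matrix(
    aligned_set: list[AlignedTMD], position_range=None
) -> FrequencyMatrix:
    """Residue frequency at each oriented position, normalized per position
    over the proteins that have a residue there."""
    if not aligned_set:
        raise ValueError("frequency_matrix requires a non-empty set")
    positions = list(position_range) if position_range is not None else list(
        _position_range(aligned_set)
    )
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((len(positions), len(AMINO_ACIDS)))
    for row, pos in enumerate(positions):
        for aligned in aligned_set:
            residue = aligned.residue(pos)
            if residue is not None:
                counts[row, index[residue]] += 1
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        fractions = np.where(totals[:, None] > 0, counts / np.where(totals == 0, 1, totals)[:, None], 0.0)
    return FrequencyMatrix(
        abundance=pd.DataFrame(fractions, index=positions, columns=list(AMINO_ACIDS)),
        counts=pd.Series(totals.astype(int), index=positions),
    )


def _collect(aligned_set, positions, table):
    """Per-position lists of property values over contributing proteins."""
    values: dict[int, list[float]] = {p: [] for p in positions}
    for aligned in aligned_set:
        for pos in positions:
            residue = aligned.residue(pos)
            if residue is None:
                continue
            try:
                values[pos].append(table[residue])
            except KeyError:
                raise KeyError(f"residue {residue!r} absent from property table") from None
    return values


def positional_profile(
    aligned_set: list[AlignedTMD],
    property_table,
    position_range=None,
    min_count: int = 10,
) -> PositionalProfile:
    """Mean and SEM of a per-residue property at each oriented position.

    ``property_table`` is any mapping residue -> value (a hydrophobicity
    scale or a residue-volume table). Positions where fewer than
    ``min_count`` proteins contribute are dropped to avoid noisy flank
    tails; pass ``min_count=1`` to keep everything.
    """
    if not aligned_set:
        raise ValueError("positional_profile requires a non-empty set")
    positions = list(position_range) if position_range is not None else list(
        _position_range(aligned_set)
    )
    values = _collect(aligned_set, positions, property_table)
    kept = [p for p in positions if len(values[p]) >= max(min_count, 1)]
    mean = pd.Series({p: float(np.mean(values[p])) for p in kept})
    sem = pd.Series(
        {p: float(np.std(values[p], ddof=1) / np.sqrt(len(values[p]))) if len(values[p]) > 1 else 0.0
         for p in kept}
    )
    n = pd.Series({p: len(values[p]) for p in kept})
    return PositionalProfile(mean=mean, sem=sem, n=n)


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-sample t test with the zero-difference convention: identical
    means give t = 0, p = 1 even when both samples are constant."""
    if np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_profiles(
    set_a: list[AlignedTMD],
    set_b: list[AlignedTMD],
    property_table,
    position_range=None,
    equal_var: bool = True,
    min_count: int = 2,
) -> pd.DataFrame:
    """Per-position two-sample t test of a property between two aligned sets.

    The classic pooled-variance test by default (``equal_var=True``);
    Welch's correction available as an option. Positions where either set
    has fewer than two observations get NaN statistics rather than raising.
    Returns a DataFrame with columns ``mean_a``, ``mean_b``, ``diff``
    (a − b), ``t``, ``p``, ``n_a``, ``n_b`` indexed by position.
    """
    if not set_a or not set_b:
        raise ValueError("compare_profiles requires two non-empty sets")
    if position_range is not None:
        positions = list(position_range)
    else:
        lo = min(_position_range(set_a).start, _position_range(set_b).start)
        hi = max(_position_range(set_a).stop, _position_range(set_b).stop)
        positions = list(range(lo, hi))
    values_a = _collect(set_a, positions, property_table)
    values_b = _collect(set_b, positions, property_table)
    rows = []
    for pos in positions:
        a, b = np.asarray(values_a[pos]), np.asarray(values_b[pos])
        if len(a) < max(min_count, 2) or len(b) < max(min_count, 2):
            rows.append((pos, np.nan, np.nan, np.nan, np.nan, np.nan, len(a), len(b)))
            continue
        t, p = _ttest(a, b, equal_var)
        rows.append((pos, a.mean(), b.mean(), a.mean() - b.mean(), t, p, len(a), len(b)))
    frame = pd.DataFrame(
        rows, columns=["position", "mean_a", "mean_b", "diff", "t", "p", "n_a", "n_b"]
    ).set_index("position")
    return frame


def compare_lengths(
    dist_a: LengthDistribution, dist_b: LengthDistribution, equal_var: bool = True
) -> tuple[float, float, float]:
    """Single two-sample t test on two hydrophobic-length distributions.

    Returns ``(mean difference a − b, t, p)``.
    """
    a, b = dist_a.values(), dist_b.values()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("length comparison requires at least two lengths per set")
    t, p = _ttest(a, b, equal_var)
    return float(a.mean() - b.mean()), t, p


def length_distribution(annotations: list[TMDAnnotation]) -> LengthDistribution:
    """Exact histogram and mean of hydrophobic lengths."""
    if not annotations:
        raise ValueError("length_distribution requires a non-empty list")
    lengths = [a.hydrophobic_length for a in annotations]
    return LengthDistribution(
        histogram=dict(Counter(lengths)),
        mean=float(np.mean(lengths)),
        n=len(lengths),
    )
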