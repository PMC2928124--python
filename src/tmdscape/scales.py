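"""Hydrophobicity scales and residue volumes.

All per-residue property tables live here, loaded from the TSV files shipped
under :mod:`tmdscape.data`. Every hydrophobicity scale is stored in a single
sign convention: **negative values mean the residue prefers the interior of a
lipid bilayer**, positive values mean it prefers water. The data files
document the published source of each table and whether a sign flip was
applied to reach this convention.

Three scales are provided:

``GES``
    Engelman-Steitz-Goldman transfer free energies. The default scale for
    edge scanning, with a window threshold of -0.94 kcal/mol and an
    individual-residue threshold of 8.0 kcal/mol (exceeded only by D, E, K
    and R).
``WimleyWhite``
    Water-to-octanol transfer free energies; window threshold -0.50
    kcal/mol, individual threshold 3.60 kcal/mol (D, E).
``Biological``
    Translocon-measured apparent insertion free energies; window threshold
    0.20 kcal/mol, individual threshold 2.70 kcal/mol (D, K).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "AMINO_ACIDS",
    "HydrophobicityScale",
    "GES",
    "WIMLEY_WHITE",
    "BIOLOGICAL",
    "SCALES",
    "get_scale",
    "residue_volumes",
]

#: The 20 standard amino acids, in the fixed alphabetical one-letter order
#: used everywhere a residue axis is laid out (frequency matrices, encodings).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"


def _load_table(filename: str, column: str) -> dict[str, float]:
    values: dict[str, float] = {}
    text = resources.files("tmdscape.data").joinpath(filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        residue, value = line.split("\t")
        values[residue] = float(value)
    missing = set(AMINO_ACIDS) - set(values)
    if missing:
        raise ValueError(f"{filename} is missing residues {sorted(missing)}")
    return values


@dataclass(frozen=True)
class HydrophobicityScale:
    """A per-residue free-energy table plus the edge-scanning thresholds.

    Parameters
    ----------
    name
        Scale identifier (``"GES"``, ``"WimleyWhite"`` or ``"Biological"``).
    values
        Mapping residue -> kcal/mol, negative = bilayer-preferring.
    window_threshold
        A scanning window belongs to the hydrophobic core while its mean
        value is at or below this threshold (kcal/mol).
    residue_threshold
        An individual residue terminates the core outright when its value
        exceeds this threshold (kcal/mol); for each scale it sits just below
        the most hydrophilic (charged) residues.
    window
        Width of the scanning window in residues (odd, centered).
    indent
        How far the scan start is indented from the guide edge toward the
        TMD center.
    """

    name: str
    values: dict[str, float] = field(repr=False)
    window_threshold: float
    residue_threshold: float
    window: int = 5
    indent: int = 4

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues {sorted(missing)}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


GES = HydrophobicityScale(
    name="GES",
    values=_load_table("ges.tsv", "value"),
    window_threshold=-0.94,
    residue_threshold=8.0,
)

WIMLEY_WHITE = HydrophobicityScale(
    name="WimleyWhite",
    values=_load_table("wimley_white.tsv", "value"),
    window_threshold=-0.50,
    residue_threshold=3.60,
)

BIOLOGICAL = HydrophobicityScale(
    name="Biological",
    values=_load_table("biological.tsv", "value"),
    window_threshold=0.20,
    residue_threshold=2.70,
)

SCALES: dict[str, HydrophobicityScale] = {
    "ges": GES,
    "ww": WIMLEY_WHITE,
    "wimleywhite": WIMLEY_WHITE,
    "bio": BIOLOGICAL,
    "biological": BIOLOGICAL,
}


def get_scale(name: str) -> HydrophobicityScale:
    """Look up a scale by name (case-insensitive; ``ges``/``ww``/``bio``)."""
    try:
        return SCALES[name.lower().replace("-", "").replace("_", "")]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; available: ges, ww (WimleyWhite), bio (Biological)"
        ) from None


def residue_volumes() -> dict[str, float]:
    """Published mean residue volumes in cubic Angstroms (Gly smallest)."""
    return dict(_VOLUMES)


_VOLUMES = _load_table("volumes.tsv", "volume")
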