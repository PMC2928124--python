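"""Synthetic organelle-labelled bitopic proteins with known ground truth.

Each :class:`OrganellePreset` emulates the statistical structure the
analysis assumes real organelle proteomes to have:

* organelle-specific hydrophobic-core length distributions — shorter for
  ER/Golgi, intermediate for TGN/endosomes, longer for the plasma membrane
  (default means 20/19/22/26 residues, spread ±2, reproducing the several-
  residue early-vs-late secretory pathway gap);
* leaflet-asymmetric core compositions — the exoplasmic (outer) half of
  PM-like cores is enriched in small residues (G, A, S, V) and of
  Golgi-like cores in large ones (F, L, I), on a shared hydrophobic
  background;
* positive-inside charged cytosolic flanks (K/R-enriched bulk);
* an optional serine-rich lumenal linker for Golgi-like sets.

Flank models distinguish a 2-residue *interface* pool (the residues
immediately adjacent to the core: uncharged, mixed mildly-polar/polar) from
the *bulk* pool beyond it. This mirrors real interface enrichment and keeps
the generated edges sharp: charged and strongly polar residues sit where
they terminate the hydrophobicity scan, not inside the scanning window at
the true edge, so the scanned core length is recoverable from clean draws.

Every protein carries a :class:`SyntheticTruth` record holding the true
core interval; the guide interval handed to downstream edge refinement is
the truth perturbed by up to ±2 residues per edge.

All randomness flows through one explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .proteins import BitopicProtein, OrganelleDataset
from .datasets import pairwise_identity
from .scales import AMINO_ACIDS

__all__ = [
    "FlankModel",
    "OrganellePreset",
    "SyntheticTruth",
    "DEFAULT_PRESETS",
    "calibration_preset",
    "sample_protein",
    "sample_dataset",
    "make_redundant_family",
]


def _normalize(composition: dict[str, float]) -> dict[str, float]:
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition sums to {total}, not 1")
    return dict(composition)


@dataclass(frozen=True)
class FlankModel:
    """Composition model for one flank of the TMD.

    ``interface`` residues fill the ``interface_width`` positions adjacent
    to the hydrophobic core; ``bulk`` residues fill the rest, out to
    ``length`` residues total.
    """

    length: int
    bulk: dict[str, float]
    interface: dict[str, float]
    interface_width: int = 2

    def __post_init__(self) -> None:
        _normalize(self.bulk)
        _normalize(self.interface)
        if self.length < self.interface_width:
            raise ValueError("flank shorter than its interface region")


@dataclass(frozen=True)
class OrganellePreset:
    """Generative model of one organelle's single-pass TMD population."""

    name: str
    core_length_mean: float
    core_length_sd: float
    inner_composition: dict[str, float]
    outer_composition: dict[str, float]
    cytosolic_flank: FlankModel
    exoplasmic_flank: FlankModel
    topology_mix: dict[str, float] = field(
        default_factory=lambda: {"I": 0.3, "II": 0.6, "III": 0.1}
    )

    def __post_init__(self) -> None:
        _normalize(self.inner_composition)
        _normalize(self.outer_composition)
        _normalize(self.topology_mix)
        if self.core_length_mean < 10:
            raise ValueError("core length mean must be >= 10")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded at generation time, for recovery tests."""

    protein_id: str
    true_core_interval: tuple[int, int]
    organelle: str
    preset: str


def _draw(composition: dict[str, float], n: int, rng: np.random.Generator) -> str:
    residues = list(composition)
    probs = np.array([composition[r] for r in residues])
    probs = probs / probs.sum()
    return "".join(rng.choice(residues, size=n, p=probs))


def _draw_flank(model: FlankModel, rng: np.random.Generator) -> tuple[str, str]:
    """Returns (bulk part, interface part); interface is core-adjacent."""
    bulk = _draw(model.bulk, model.length - model.interface_width, rng)
    interface = _draw(model.interface, model.interface_width, rng)
    return bulk, interface


def _ges_sum(residues: str) -> float:
    from .scales import GES

    return sum(GES[r] for r in residues)


def _sharpen_edge(
    core3: str,
    flank_model: FlankModel,
    rng: np.random.Generator,
    tries: int = 300,
) -> tuple[str, str]:
    """Redraw the interface pair and nearest bulk residue until the core
    boundary is crisp under the 5-residue window rule.

    ``core3`` is the three core residues nearest the edge, read from the
    flank inward. Returns ``(nearest bulk residue, interface pair)`` such
    that the window centered on the last core residue is hydrophobic (mean
    <= -0.94 kcal/mol, GES) while the window one step into the flank is
    not. This makes the generative core interval the operational truth: the
    hydrophobic stretch really does end where the label says, rather than
    at whatever offset the local draw noise produced.
    """
    from .scales import GES

    limit = 5 * GES.window_threshold
    core_in = _ges_sum(core3)      # c1+c2+c3, window at the edge residue
    core_out = _ges_sum(core3[:2])  # c1+c2, window one step out
    for _ in range(tries):
        iface = _draw(flank_model.interface, flank_model.interface_width, rng)
        bulk1 = _draw(flank_model.bulk, 1, rng)
        if _ges_sum(iface) + core_in <= limit and _ges_sum(bulk1 + iface) + core_out > limit:
            return bulk1, iface
    raise RuntimeError(
        "could not sharpen a core boundary; core edge residues too hydrophilic"
    )


def sample_protein(
    preset: OrganellePreset,
    rng: np.random.Generator,
    protein_id: str = "synth",
) -> tuple[BitopicProtein, SyntheticTruth]:
    """Draw one protein: topology, core length, leaflet-specific core halves,
    and both flanks; the guide interval is the true core perturbed by up to
    ±2 residues per edge."""
    topologies = sorted(preset.topology_mix)
    topology = str(
        rng.choice(topologies, p=[preset.topology_mix[t] for t in topologies])
    )
    spread = int(round(preset.core_length_sd))
    length = max(10, int(preset.core_length_mean) + int(rng.integers(-spread, spread + 1)))
    inner = _draw(preset.inner_composition, length // 2, rng)
    outer = _draw(preset.outer_composition, length - length // 2, rng)

    cyt_bulk, _ = _draw_flank(preset.cytosolic_flank, rng)
    exo_bulk, _ = _draw_flank(preset.exoplasmic_flank, rng)
    # crisp boundaries: the residues spanning each core edge are redrawn so
    # that the hydrophobic stretch ends exactly at the true interval
    cyt_bulk1, cyt_iface = _sharpen_edge(inner[:3], preset.cytosolic_flank, rng)
    exo_bulk1, exo_iface = _sharpen_edge(outer[::-1][:3], preset.exoplasmic_flank, rng)
    cyt_bulk = cyt_bulk[:-1] + cyt_bulk1 if len(cyt_bulk) else cyt_bulk1
    exo_bulk = exo_bulk1 + exo_bulk[1:] if len(exo_bulk) else exo_bulk1

    # construct cytosol->exoplasm, then lay onto the N->C sequence by topology
    oriented = cyt_bulk + cyt_iface + inner + outer + exo_iface + exo_bulk
    core_start_oriented = len(cyt_bulk) + len(cyt_iface) + 1
    core_end_oriented = core_start_oriented + length - 1
    if topology == "II":
        sequence = oriented
        true_start, true_end = core_start_oriented, core_end_oriented
    else:  # types I and III: N terminus exoplasmic, so reverse
        sequence = oriented[::-1]
        true_start = len(oriented) - core_end_oriented + 1
        true_end = len(oriented) - core_start_oriented + 1

    jitter = rng.integers(-2, 3, size=2)
    guide_start = int(np.clip(true_start + jitter[0], 1, len(sequence)))
    guide_end = int(np.clip(true_end + jitter[1], 1, len(sequence)))
    if guide_end - guide_start + 1 < 10:  # keep the guide scannable
        guide_start, guide_end = true_start, true_end

    protein = BitopicProtein(
        id=protein_id,
        sequence=sequence,
        topology=topology,
        organelle=preset.name,
        guide_tmd=(guide_start, guide_end),
        species_tag="synthetic",
    )
    truth = SyntheticTruth(
        protein_id=protein_id,
        true_core_interval=(true_start, true_end),
        organelle=preset.name,
        preset=preset.name,
    )
    return protein, truth


def sample_dataset(
    preset: OrganellePreset, n: int, seed: int | np.random.Generator
) -> tuple[OrganelleDataset, list[SyntheticTruth]]:
    """Draw ``n`` independent proteins, reproducible from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proteins, truths = [], []
    for i in range(n):
        protein, truth = sample_protein(preset, rng, protein_id=f"{preset.name}_{i:04d}")
        proteins.append(protein)
        truths.append(truth)
    dataset = OrganelleDataset(
        organelle=preset.name,
        proteins=proteins,
        provenance=f"synthetic preset {preset.name!r}, n={n}",
    )
    return dataset, truths


def make_redundant_family(
    base_protein: BitopicProtein,
    n: int,
    target_identity: float,
    rng: np.random.Generator,
    flank: int = 10,
    tolerance: float = 0.05,
) -> list[BitopicProtein]:
    """Mutated copies of a protein at a controlled identity to the base.

    Substitutions are placed uniformly at random within the guide-TMD core
    plus ``flank`` residues per side — the region redundancy reduction
    measures identity over — until each copy's global-alignment identity to
    the base over that region is within ``tolerance`` of
    ``target_identity`` (verified, with retries; raises if unattainable for
    the region length).
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    start, end = base_protein.guide_tmd
    lo = max(1, start - flank)
    hi = min(len(base_protein.sequence), end + flank)
    region_len = hi - lo + 1
    if 1.0 / region_len > tolerance * 2 and target_identity < 1:
        raise ValueError(
            f"region of {region_len} residues too short to hit identity "
            f"{target_identity:.2f} within ±{tolerance:.2f}"
        )
    base_region = base_protein.sequence[lo - 1 : hi]
    alphabet = list(AMINO_ACIDS)

    family = []
    for i in range(n):
        if target_identity == 1.0:
            mutated_sequence = base_protein.sequence
        else:
            m = int(round((1 - target_identity) * region_len))
            mutated_sequence = None
            for _attempt in range(50):
                positions = rng.choice(region_len, size=min(m, region_len), replace=False)
                region = list(base_region)
                for p in positions:
                    choices = [a for a in alphabet if a != base_region[p]]
                    region[p] = choices[int(rng.integers(len(choices)))]
                candidate = (
                    base_protein.sequence[: lo - 1] + "".join(region) + base_protein.sequence[hi:]
                )
                identity = pairwise_identity(base_region, "".join(region))
                if abs(identity - target_identity) <= tolerance:
                    mutated_sequence = candidate
                    break
                m = min(region_len, max(1, m + (1 if identity > target_identity else -1)))
            if mutated_sequence is None:
                raise ValueError(
                    f"could not reach identity {target_identity:.2f} ± {tolerance:.2f} "
                    f"over a {region_len}-residue region"
                )
        family.append(
            BitopicProtein(
                id=f"{base_protein.id}|fam{i}",
                sequence=mutated_sequence,
                topology=base_protein.topology,
                organelle=base_protein.organelle,
                guide_tmd=base_protein.guide_tmd,
                species_tag=base_protein.species_tag,
            )
        )
    return family


# --------------------------------------------------------------------------
# Default presets: the study conditions every calibrated assertion runs under.
# Compositions are perturbations of a shared hydrophobic background
# (L/I/V/F/A-rich); see docs/methods.md for the rationale behind each number.

#: Hydrophobic background; the shared base every core half perturbs.
CORE_BACKGROUND: dict[str, float] = {
    "L": 0.32, "I": 0.16, "V": 0.14, "F": 0.12, "A": 0.12,
    "M": 0.05, "G": 0.03, "S": 0.03, "T": 0.02, "C": 0.01,
}

#: ER core halves: background with a Met/Cys signature.
_ER_CORE: dict[str, float] = {
    "L": 0.26, "I": 0.13, "V": 0.11, "F": 0.09, "A": 0.10,
    "M": 0.12, "C": 0.06, "G": 0.04, "S": 0.05, "T": 0.04,
}

#: TGN/endosome core halves: beta-branched (Ile/Val) signature.
_TGN_INNER: dict[str, float] = {
    "L": 0.22, "I": 0.26, "V": 0.22, "F": 0.08, "A": 0.08,
    "M": 0.03, "G": 0.03, "S": 0.04, "T": 0.03, "C": 0.01,
}

#: PM inner half: leucine/phenylalanine-enriched relative to background,
#: the inner-leaflet large-residue signature of plasma-membrane TMDs.
_PM_INNER: dict[str, float] = {
    "L": 0.38, "I": 0.16, "V": 0.12, "F": 0.14, "A": 0.08,
    "M": 0.05, "G": 0.02, "S": 0.03, "T": 0.01, "C": 0.01,
}

#: PM outer half: shifted toward small residues (thicker, ordered outer leaflet).
_PM_OUTER: dict[str, float] = {
    "V": 0.28, "C": 0.05, "G": 0.08, "A": 0.12, "S": 0.06, "L": 0.18,
    "I": 0.10, "F": 0.04, "T": 0.04, "M": 0.05,
}

#: Golgi outer half: shifted toward large residues, aromatic-rich.
_GOLGI_OUTER: dict[str, float] = {
    "F": 0.24, "L": 0.34, "I": 0.16, "V": 0.10, "A": 0.04, "M": 0.04,
    "W": 0.06, "G": 0.01, "S": 0.01,
}

#: TGN/endosome outer half: beta-branched with an intermediate small-residue
#: shift (between the Golgi and PM extremes).
_TGN_OUTER: dict[str, float] = {
    "I": 0.26, "V": 0.28, "L": 0.19, "A": 0.06, "G": 0.03, "S": 0.03,
    "F": 0.07, "T": 0.04, "M": 0.02, "C": 0.02,
}

#: Cytosolic interface (2 residues adjacent to the core): uncharged polar.
_CYT_INTERFACE: dict[str, float] = {
    "N": 0.14, "Q": 0.10, "S": 0.22, "G": 0.16, "T": 0.14, "P": 0.10, "A": 0.14,
}

#: Cytosolic bulk flanks: positive-inside K/R enrichment, whose density
#: rises along the secretory pathway (weakest for ER, strongest for PM).
_CYT_BULK_ER: dict[str, float] = {
    "K": 0.16, "R": 0.12, "N": 0.14, "Q": 0.08, "S": 0.14,
    "G": 0.10, "T": 0.08, "A": 0.10, "P": 0.08,
}
_CYT_BULK_GOLGI: dict[str, float] = {
    "K": 0.22, "R": 0.22, "N": 0.10, "Q": 0.06, "S": 0.10,
    "G": 0.08, "T": 0.06, "A": 0.08, "P": 0.08,
}
_CYT_BULK_TGN: dict[str, float] = {
    "K": 0.30, "R": 0.24, "N": 0.08, "Q": 0.05, "S": 0.08,
    "G": 0.06, "T": 0.05, "A": 0.07, "P": 0.07,
}
_CYT_BULK_PM: dict[str, float] = {
    "K": 0.40, "R": 0.28, "N": 0.06, "Q": 0.04, "S": 0.06,
    "G": 0.04, "T": 0.04, "A": 0.04, "P": 0.04,
}

#: Lumenal interface, shared by all presets.
_EXO_INTERFACE: dict[str, float] = {
    "N": 0.22, "Q": 0.13, "S": 0.18, "G": 0.13, "T": 0.12, "P": 0.10, "A": 0.12,
}

#: Lumenal bulk flanks: acidic for ER, amide-rich for TGN/endosomes,
#: mixed for PM, serine-rich linker for Golgi.
_EXO_BULK_ER: dict[str, float] = {
    "D": 0.26, "E": 0.26, "N": 0.14, "S": 0.10, "G": 0.08,
    "T": 0.04, "P": 0.08, "A": 0.04,
}
_EXO_BULK_TGN: dict[str, float] = {
    "D": 0.14, "E": 0.12, "N": 0.22, "Q": 0.10, "S": 0.14,
    "G": 0.08, "T": 0.06, "P": 0.10, "A": 0.04,
}
_EXO_BULK_PM: dict[str, float] = {
    "D": 0.18, "E": 0.16, "N": 0.14, "S": 0.16, "G": 0.10,
    "T": 0.08, "P": 0.10, "A": 0.08,
}
_GOLGI_LINKER_BULK: dict[str, float] = {
    "S": 0.40, "T": 0.10, "D": 0.12, "E": 0.10, "N": 0.14, "G": 0.06, "P": 0.08,
}


def _cyt_flank(bulk: dict[str, float]) -> FlankModel:
    return FlankModel(length=12, bulk=bulk, interface=_CYT_INTERFACE)


def _exo_flank(bulk: dict[str, float]) -> FlankModel:
    return FlankModel(length=14, bulk=bulk, interface=_EXO_INTERFACE)


DEFAULT_PRESETS: dict[str, OrganellePreset] = {
    "fungal-er": OrganellePreset(
        name="ER",
        core_length_mean=20, core_length_sd=2,
        inner_composition=_ER_CORE,
        outer_composition=_ER_CORE,
        cytosolic_flank=_cyt_flank(_CYT_BULK_ER),
        exoplasmic_flank=_exo_flank(_EXO_BULK_ER),
    ),
    "fungal-golgi": OrganellePreset(
        name="Golgi",
        core_length_mean=19, core_length_sd=2,
        inner_composition=CORE_BACKGROUND,
        outer_composition=_GOLGI_OUTER,
        cytosolic_flank=_cyt_flank(_CYT_BULK_GOLGI),
        exoplasmic_flank=_exo_flank(_GOLGI_LINKER_BULK),
    ),
    "fungal-tgn": OrganellePreset(
        name="TGN/endosomes",
        core_length_mean=22, core_length_sd=2,
        inner_composition=_TGN_INNER,
        outer_composition=_TGN_OUTER,
        cytosolic_flank=_cyt_flank(_CYT_BULK_TGN),
        exoplasmic_flank=_exo_flank(_EXO_BULK_TGN),
    ),
    "fungal-pm": OrganellePreset(
        name="PM",
        core_length_mean=26, core_length_sd=2,
        inner_composition=_PM_INNER,
        outer_composition=_PM_OUTER,
        cytosolic_flank=_cyt_flank(_CYT_BULK_PM),
        exoplasmic_flank=_exo_flank(_EXO_BULK_PM),
    ),
}


def calibration_preset() -> OrganellePreset:
    """A neutral, length-graded preset for scanner cross-checks.

    Core halves both use the shared hydrophobic background and the true core
    length is spread widely (discrete uniform 16..30), so the dominant
    between-protein signal is length itself. This isolates properties of the
    edge-scanning machinery — e.g. cross-scale length consistency — from the
    organelle-specific composition biases of the default presets, which
    interact with each scale's absolute thresholds.
    """
    er = DEFAULT_PRESETS["fungal-er"]
    return OrganellePreset(
        name="calibration",
        core_length_mean=23, core_length_sd=7,
        inner_composition=CORE_BACKGROUND,
        outer_composition=CORE_BACKGROUND,
        cytosolic_flank=er.cytosolic_flank,
        exoplasmic_flank=er.exoplasmic_flank,
    )
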