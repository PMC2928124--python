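"""Curation of organelle-labelled protein sets.

Reading/writing of FASTA + annotation-TSV pairs, the ortholog quality
filters (length deviation, minimum TMD hydrophobicity, exact-duplicate
removal), pairwise identity over TMD regions, and single-linkage redundancy
reduction so that no two retained proteins exceed 30% identity over the
hydrophobic core plus 10 residues of flanking sequence.

Annotation tables are TSV with header
``id  topology  organelle  tmd_start  tmd_end  species`` and 1-based
inclusive intervals; topology is one of I, II, III.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proteins import BitopicProtein, OrganelleDataset
from .scales import HydrophobicityScale
from .tmd_edges import TMDAnnotation

__all__ = [
    "AnnotationError",
    "load_annotated_set",
    "write_annotated_set",
    "filter_candidates",
    "pairwise_identity",
    "reduce_redundancy",
    "equalize_sets",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["id", "topology", "organelle", "tmd_start", "tmd_end", "species"]


class AnnotationError(ValueError):
    """A malformed or inconsistent annotation row, naming the record."""


def load_annotated_set(fasta_path, annotation_path) -> list[OrganelleDataset]:
    """Read a FASTA + annotation-TSV pair into per-organelle datasets.

    Every annotation row must reference a FASTA record id; FASTA records
    never referenced are ignored with a logged warning. Returns one
    :class:`OrganelleDataset` per distinct organelle label, sorted by label.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    try:
        table = pd.read_csv(annotation_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=ANNOTATION_COLUMNS)
    missing_cols = set(ANNOTATION_COLUMNS[:5]) - set(table.columns)
    if missing_cols:
        raise AnnotationError(f"annotation table missing column(s) {sorted(missing_cols)}")

    proteins: list[BitopicProtein] = []
    for row in table.itertuples(index=False):
        pid = row.id
        if pid not in sequences:
            raise AnnotationError(f"annotation references id {pid!r} absent from FASTA")
        try:
            start, end = int(row.tmd_start), int(row.tmd_end)
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"protein {pid!r}: malformed interval "
                                  f"({row.tmd_start!r}, {row.tmd_end!r})") from exc
        species = getattr(row, "species", None)
        if species is not None and (pd.isna(species) or species == ""):
            species = None
        try:
            proteins.append(
                BitopicProtein(
                    id=pid,
                    sequence=sequences[pid],
                    topology=row.topology,
                    organelle=row.organelle,
                    guide_tmd=(start, end),
                    species_tag=species,
                )
            )
        except ValueError as exc:
            raise AnnotationError(str(exc)) from exc

    unreferenced = set(sequences) - {p.id for p in proteins}
    if unreferenced:
        logger.warning(
            "%d FASTA record(s) not referenced by any annotation row ignored: %s",
            len(unreferenced),
            ", ".join(sorted(unreferenced)[:5]) + ("..." if len(unreferenced) > 5 else ""),
        )

    datasets = []
    for organelle in sorted({p.organelle for p in proteins}):
        members = [p for p in proteins if p.organelle == organelle]
        datasets.append(
            OrganelleDataset(
                organelle=organelle,
                proteins=members,
                provenance=f"loaded from {Path(str(fasta_path)).name}",
            )
        )
    return datasets


def write_annotated_set(datasets: list[OrganelleDataset], fasta_path, annotation_path) -> None:
    """Write datasets back to a FASTA + annotation-TSV pair (round-trips
    through :func:`load_annotated_set`)."""
    records = []
    rows = []
    for dataset in datasets:
        for p in dataset:
            records.append(SeqRecord(Seq(p.sequence), id=p.id, description=""))
            rows.append(
                {
                    "id": p.id,
                    "topology": p.topology,
                    "organelle": p.organelle,
                    "tmd_start": p.guide_tmd[0],
                    "tmd_end": p.guide_tmd[1],
                    "species": p.species_tag or "",
                }
            )
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(annotation_path, sep="\t", index=False)


def _best_window_mean(region: str, scale: HydrophobicityScale, width: int = 10) -> float:
    """Mean scale value of the most hydrophobic (lowest-mean) ``width``-residue
    window in ``region``."""
    if len(region) < width:
        raise ValueError(f"region shorter than window width {width}")
    values = np.array([scale[r] for r in region])
    sums = np.convolve(values, np.ones(width), mode="valid")
    return float(sums.min() / width)


def filter_candidates(
    candidates: list[BitopicProtein],
    reference: BitopicProtein,
    scale: HydrophobicityScale,
    length_tolerance: int = 100,
    hydrophobicity_threshold: float = -0.95,
    window: int = 10,
) -> list[BitopicProtein]:
    """Apply the ortholog quality filters against a reference protein.

    A candidate is retained when (a) its total length is within
    ``length_tolerance`` residues of the reference, (b) the most hydrophobic
    ``window``-residue stretch inside its guide interval has mean hydropathy
    at or below ``hydrophobicity_threshold`` kcal/mol (negative =
    hydrophobic), and (c) its sequence is not an exact duplicate of an
    earlier retained candidate. Rejections are logged with a reason.
    """
    retained: list[BitopicProtein] = []
    seen_sequences: set[str] = set()
    for candidate in candidates:
        if abs(len(candidate.sequence) - len(reference.sequence)) > length_tolerance:
            logger.info("rejected %s: length deviates by more than %d residues",
                        candidate.id, length_tolerance)
            continue
        guide = candidate.guide_region()
        if len(guide) < window:
            logger.info("rejected %s: guide interval shorter than %d residues",
                        candidate.id, window)
            continue
        if _best_window_mean(guide, scale, window) > hydrophobicity_threshold:
            logger.info("rejected %s: best %d-residue window mean above %.2f kcal/mol",
                        candidate.id, window, hydrophobicity_threshold)
            continue
        if candidate.sequence in seen_sequences:
            logger.info("rejected %s: exact duplicate sequence", candidate.id)
            continue
        seen_sequences.add(candidate.sequence)
        retained.append(candidate)
    return retained


# Global (Needleman-Wunsch) alignment: match=1, mismatch=0, linear gap -1.
# Identity = matches / alignment columns. The original study used BLASTClust,
# whose exact scoring is not published; this transparent scheme is fixed here.
_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in an optimal global alignment of two
    region strings; symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty strings")
    alignment = _aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


def _tmd_region(protein: BitopicProtein, flank: int,
                annotation: TMDAnnotation | None) -> str:
    if annotation is not None:
        lo = min(annotation.cytosolic_edge, annotation.exoplasmic_edge)
        hi = max(annotation.cytosolic_edge, annotation.exoplasmic_edge)
        lo = max(1, lo - flank)
        hi = min(len(protein.sequence), hi + flank)
        return protein.sequence[lo - 1 : hi]
    return protein.guide_region(flank)


def reduce_redundancy(
    dataset: OrganelleDataset,
    identity_threshold: float = 0.30,
    flank: int = 10,
    seed: int | np.random.Generator = 0,
    annotations: dict[str, TMDAnnotation] | None = None,
) -> OrganelleDataset:
    """Single-linkage redundancy reduction over TMD core + flank regions.

    Proteins whose region identity exceeds ``identity_threshold`` are linked;
    connected components form clusters and one random representative per
    cluster is retained (seeded). Every retained pair therefore has identity
    at or below the threshold. ``annotations`` optionally supplies scanned
    core edges per protein id; otherwise the guide interval defines the core.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proteins = list(dataset.proteins)
    n = len(proteins)
    regions = [
        _tmd_region(p, flank, annotations.get(p.id) if annotations else None)
        for p in proteins
    ]

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(regions[i], regions[j]) > identity_threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    # order clusters by smallest member index so the choice of representative
    # depends only on the seed, not on dict iteration order
    chosen = []
    for root in sorted(clusters, key=lambda r: min(clusters[r])):
        members = clusters[root]
        chosen.append(members[int(rng.integers(len(members)))])
    kept = [proteins[i] for i in sorted(chosen)]
    return OrganelleDataset(
        organelle=dataset.organelle,
        proteins=kept,
        provenance=(dataset.provenance + "; " if dataset.provenance else "")
        + f"redundancy-reduced at {identity_threshold:.0%} identity",
    )


def equalize_sets(
    datasets: list[OrganelleDataset], seed: int | np.random.Generator = 0
) -> list[OrganelleDataset]:
    """Randomly down-sample all datasets to the size of the smallest.

    Balanced class sizes stop a classifier trained on these sets from being
    biased toward the largest organelle. Uniform without-replacement removal,
    reproducible from ``seed``.
    """
    if not datasets:
        raise ValueError("no datasets given")
    if any(len(d) == 0 for d in datasets):
        empty = [d.organelle for d in datasets if len(d) == 0]
        raise ValueError(f"cannot equalize with empty dataset(s): {empty}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = min(len(d) for d in datasets)
    out = []
    for dataset in datasets:
        if len(dataset) == target:
            out.append(dataset)
            continue
        keep = sorted(rng.choice(len(dataset), size=target, replace=False))
        out.append(
            OrganelleDataset(
                organelle=dataset.organelle,
                proteins=[dataset.proteins[i] for i in keep],
                provenance=(dataset.provenance + "; " if dataset.provenance else "")
                + f"down-sampled to {target}",
            )
        )
    return out
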