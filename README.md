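# tmdscape

Comparative positional analysis of single-pass (bitopic) transmembrane
domains (TMDs). Proteins residing in different organelles of the secretory
pathway carry TMDs with systematically different physical properties —
hydrophobic length, residue volume, and how those properties are split
between the two bilayer leaflets. `tmdscape` implements the full analysis
chain that exposes these signals and turns them into a classifier of
subcellular location, for sequence bioinformaticians studying membrane-
protein sorting.

## What it computes

**Edge definition.** An approximate TMD interval (e.g. from a topology
predictor) is refined by a hydrophobicity scan: starting 4 residues inside
each guide edge, a 5-residue window centered on the candidate position
slides outward; the hydrophobic core ends at the outermost position where
the window mean stays ≤ the scale threshold and the residue itself is not
charged. The default GES scale uses a window threshold of −0.94 kcal/mol
(negative = bilayer-preferring) and an individual-residue threshold of
8.0 kcal/mol (exceeded only by D, E, K, R); Wimley–White (octanol) and the
translocon-derived "Biological" scale are provided with their own
thresholds.

**Cytosolic-edge alignment.** Each TMD is re-indexed so position 1 is the
cytosolic edge of the hydrophobic core and positions increase toward the
exoplasmic side — type II proteins read N→C, types I/III C→N. On this common
axis the package computes residue-frequency matrices, mean hydropathy and
residue-volume profiles with SEM, per-position two-sample *t* tests,
hydrophobic-length distributions, and consensus TMDs.

**Leaflet asymmetry and size moment.** The TMD is split at its midpoint into
inner (cytosolic) and outer (exoplasmic) leaflet halves; each residue type
gets the preference ratio (outer − inner)/(outer + inner) in [−1, +1]. A
helical *size moment* — the planar magnitude of residue-volume vectors
placed at 100° increments, summed over 7-residue windows — detects flattened
helix faces such as GXXXG dimerization motifs.

**Organelle classifier.** Residue compositions of six regions along the
oriented TMD, (−3–0), (1–4), (9–11), (12–15), (16–17), (18–24), form 120
inputs to a feed-forward network with 7 hidden nodes, trained by online
back-propagation (learning rate 0.01, 100 cycles). Performance is assessed
by stratified 5-fold cross-validation with per-class MCC, sensitivity
Tp/(Tp+Fn) and specificity Tp/(Tp+Fp), plus a threshold scan and a
reversed-sequence control that presents each TMD in the wrong bilayer
orientation.

**Curation.** Ortholog-style quality filters (±100-residue length deviation,
minimum TMD hydrophobicity over a 10-residue window, duplicate removal) and
single-linkage redundancy reduction so no two retained proteins exceed 30%
identity over the TMD core ± 10 flanking residues (Needleman–Wunsch global
alignment, match 1 / mismatch 0 / gap −1).

**Synthetic data.** Because the original curated ortholog sets are external,
a first-class generator emulates organelle-labelled protein populations:
organelle-specific core-length distributions (Golgi 19 < ER 20 <
TGN/endosomes 22 < PM 26, ±2), leaflet-asymmetric core compositions
(small residues outward for PM, large for Golgi), positive-inside charged
cytosolic flanks, a serine-rich Golgi lumenal linker, and near-duplicate
families for redundancy tests. Generator truths (exact core intervals) make
edge recovery measurable.

## Worked example

```python
import numpy as np
from tmdscape import GES, annotate_tmd, orient_cytosolic
from tmdscape.synthetic_data import DEFAULT_PRESETS, sample_dataset
from tmdscape.classifier import cross_validate
from tmdscape.profiles import length_distribution
from tmdscape.asymmetry import leaflet_preference

rng = np.random.default_rng(1)
sets = [sample_dataset(p, 99, rng)[0] for p in DEFAULT_PRESETS.values()]

for dataset in sets:
    aligned, annotations = [], []
    for protein in dataset:
        ann = annotate_tmd(protein, GES)
        annotations.append(ann)
        aligned.append(orient_cytosolic(protein, ann))
    dist = length_distribution(annotations)
    lp = leaflet_preference(aligned)
    print(f"{dataset.organelle:15s} mean hydrophobic length {dist.mean:5.2f}  "
          f"G ratio {lp.ratio['G']:+.2f}  F ratio {lp.ratio['F']:+.2f}")

result = cross_validate(sets, k=5, seed=1)
print(f"5-fold CV accuracy: {100*result.accuracy:.1f}%")
```

prints

```
ER              mean hydrophobic length 19.98  G ratio +0.14  F ratio -0.05
Golgi           mean hydrophobic length 18.80  G ratio -0.57  F ratio +0.37
TGN/endosomes   mean hydrophobic length 21.57  G ratio -0.21  F ratio -0.04
PM              mean hydrophobic length 25.86  G ratio +0.63  F ratio -0.52
5-fold CV accuracy: 81.1%
```

Reading it: scanned hydrophobic lengths reproduce the early-to-late
secretory gradient (Golgi shortest, plasma membrane ~7 residues longer —
about 10 Å of extra helix at 1.5 Å per residue). The leaflet ratios show PM
TMDs push glycine outward (+0.63) and phenylalanine inward (−0.52) while
Golgi TMDs do the opposite — the outer-leaflet small-residue signature. The
network recovers organelle of residence for 81% of proteins from TMD
sequence alone.

The same pipeline is scriptable from the shell:

```sh
tmdscape synth --preset fungal-pm --n 99 --seed 1 --out data/
tmdscape edges --fasta data/fungal-pm.fasta --annot data/fungal-pm.tsv --out edges.tsv
tmdscape crossval --fasta all.fasta --annot all.tsv --k 5 --seed 1
```

## Layout

- `src/tmdscape/scales.py` — hydrophobicity scales and residue volumes
  (data files under `src/tmdscape/data/` document sources and sign
  conventions)
- `src/tmdscape/tmd_edges.py` — edge scanning and bilayer orientation
- `src/tmdscape/datasets.py` — I/O, quality filters, identity, redundancy
- `src/tmdscape/profiles.py` — positional composition/property analytics
- `src/tmdscape/asymmetry.py` — leaflet ratios, size moments, consensus
- `src/tmdscape/classifier.py` — region encoding and the neural network
- `src/tmdscape/synthetic_data.py` — organelle presets and the generator
- `docs/methods.md` — model assumptions, parameter choices, limitations
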