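# Methods

This note records the models, conventions and numerical choices behind
`tmdscape`, and what the synthetic study conditions do and do not show.

## Hydrophobicity scanning

The core primitive refines a guide TMD interval into hydrophobic-core
edges. From each guide edge, the start position is indented 4 residues
toward the TMD center; a 5-residue window *centered on the candidate
position* then slides outward one residue at a time. A candidate passes
while

* the window mean is ≤ the scale's window threshold, and
* the candidate residue's own value is ≤ the individual-residue threshold
  (a rule that in practice only charged residues trigger).

The returned edge is the outermost passing candidate; the scan stops at the
first failing candidate or at a sequence terminus. Windows are truncated at
sequence termini and the mean taken over the residues that exist. If even
the indented start fails, the protein has no scannable hydrophobic core and
an error is raised; pipeline stages that process whole sets skip such
records with a warning, as curation would.

Two consequences of the centered window are worth knowing. First, strongly
hydrophilic residues just *outside* the core pull the window mean up while
the center is still inside, so edges can sit 1–2 residues inside a sharp
compositional boundary flanked by charged residues. Second, mildly
hydrophobic flank residues (S, G, A, T on the GES scale) can let the scan
creep a residue or two outward. Both behaviours are properties of the
published rule, not artifacts; the synthetic generator is designed so that
clean draws have boundaries the rule recovers (below).

### Scales

All three scales are stored so that negative = bilayer-preferring, and each
carries the thresholds the scanning rule uses:

| scale | source table | window thr. (kcal/mol) | residue thr. (kcal/mol) |
|---|---|---|---|
| GES | Engelman–Steitz–Goldman transfer free energies, sign-flipped | −0.94 | 8.0 (D, E, K, R) |
| WimleyWhite | water→octanol transfer free energies | −0.50 | 3.60 (D, E) |
| Biological | translocon insertion ΔG_app | 0.20 | 2.70 (D, K) |

The Wimley–White *octanol* variant (not the interface scale) is the one
whose two most hydrophilic residues are D (3.64) and E (3.63), matching the
3.60 individual threshold; likewise the Biological thresholds match the
published ΔG_app table (K 2.71, D 3.49). The quoted window thresholds are
used verbatim as operational constants. Data files under
`src/tmdscape/data/` record sources and sign flips.

The octanol scale rates A, G, S, T as water-preferring, so its scanner is
conservative: TMD stretches rich in small residues may fail its window rule
outright. Cross-scale consistency is therefore a property of the scanner on
neutrally composed cores, and is tested on the length-graded calibration
preset (below) rather than on the composition-biased organelle presets.

Residue volumes (Å³) are the standard published mean residue volumes
(Gly 60.1 smallest, Trp 227.8 largest).

## Orientation and coordinates

Coordinates in all file formats are 1-based inclusive on the N→C sequence.
After scanning, every TMD is re-indexed onto a bilayer frame: position 1 is
the cytosolic-edge residue and positions increase toward the exoplasmic
side. Type II proteins (N terminus cytosolic) are read N→C; types I and III
C→N. Cytosolic flank residues occupy positions ≤ 0 (position 0 adjacent to
the core) and exoplasmic flank positions > hydrophobic length. The
classifier's first encoded region, (−3–0), is thus the last four cytosolic
flank residues.

## Positional analytics

* Frequency matrices normalize per position over the proteins contributing
  a residue there; profile means/SEMs likewise use per-position n.
* Profiles drop positions with n < 10 by default (configurable) to avoid
  noisy flank tails.
* The two-sample *t* test is the classic pooled-variance test; Welch's
  correction is an option. Per-position p-values are reported raw, with no
  multiple-testing correction across positions — positions are strongly
  dependent and the plots are read as profiles, not as a discovery screen.
* Zero-variance convention: when both samples have the same mean the test
  reports t = 0, p = 1 (the generic formula is 0/0 there); with unequal
  means and zero pooled variance the p-value is 0.
* SEM uses the n−1 sample standard deviation.

## Leaflet asymmetry and size moment

The inner leaflet is positions 1..⌊L/2⌋ and the outer leaflet the rest; for
odd L the midpoint residue goes to the outer half (the split rule must
choose a side; this one keeps the halves within one residue of equal).
Abundances are normalized within each half, and the per-residue ratio
(outer − inner)/(outer + inner) is computed *per protein* and then averaged,
with SEM over proteins — matching error bars that describe protein-to-
protein spread. A residue absent from a protein contributes nothing for
that protein; a residue absent from every protein is reported missing.

Size moments place each residue as a planar vector of length = its volume
at angle n × 100° (the ideal α-helix twist), sum over 7-residue windows
(700°, almost two turns) and report the magnitude at the window's central
residue. The angular origin restarts at each window and is immaterial
because only magnitudes are reported (verified by a periodicity test).
Windows extending past available residues are skipped. A homopolymer gives
the closed form V × |Σ_{n=0..6} e^(i·n·100°)| ≈ 0.2267 V.

Consensus TMDs take the most abundant residue per position; ties break
lexicographically.

## Curation

* Pairwise identity: Needleman–Wunsch global alignment with match 1,
  mismatch 0, linear gap −1; identity = identical columns / alignment
  columns. The original clustering tool's scoring is unpublished, so this
  transparent scheme is fixed and documented; cluster memberships may
  differ from the original study's.
* Redundancy reduction: single-linkage clusters over the core + 10-residue
  flank region at > 30% identity; one seeded-random representative per
  cluster, so every retained pair is ≤ 30%.
* Ortholog filters: total sequence length within ±100 residues of the
  reference; best 10-residue window inside the guide interval ≤ −0.95
  kcal/mol (GES, sign convention as above); exact duplicate sequences
  collapsed.
* Nonstandard residues (B, Z, X, U, O) reject the record with a named
  error: silently substituting property values would bias profiles.

## Classifier

120 inputs (6 regions × 20 residue fractions; empty regions contribute a
zero block), one hidden layer of 7 logistic units, one logistic output per
class, trained by online back-propagation for exactly 100 cycles at
learning rate 0.01 from uniform ±0.5 seeded initial weights, sample order
reshuffled each epoch.

The loss is summed per-output-node cross-entropy, so the output error
signal is simply (output − target). With a squared-error loss the extra
σ′ = o(1−o) factor attenuates gradients several-fold, and at this fixed
learning rate and cycle budget the network demonstrably underfits (training
accuracy ~54% on data where a linear model reaches 77% held-out);
cross-entropy is the classic pairing and removes that pathology without
touching the published recipe constants.

Statistics: MCC, sensitivity Tp/(Tp+Fn), and specificity Tp/(Tp+Fp). The
latter is what is usually called *precision*; the name is kept because the
downstream statistics are quoted under it. MCC is defined as 0 when a
denominator factor vanishes. Multi-class performance is one-vs-rest per
class; the scalar summary is the mean per-class MCC. Cross-validation is
stratified per class and seeded; each protein is scored once by the model
trained without its fold. The confusion threshold defaults to 0.67 during
training-time bookkeeping; reported statistics use the threshold that
maximizes pooled one-vs-rest MCC over a 0.01-step grid.

The `reverse` prediction flag mirrors a protein: the residue string is
reversed (guide mirrored) while the topology label is kept, so re-annotation
presents the TMD in the wrong bilayer orientation. (Reversing the string
*and* flipping the topology class would cancel out — the orientation code
already reads types I/III backwards.) A network that has learned genuine
leaflet asymmetry degrades on mirrored input; a palindromic TMD scores
identically either way.

## Synthetic study conditions

The generator's defaults are the fixed conditions every calibrated
assertion runs under. Four fungal-like presets:

| preset | core mean ± spread | outer-half signature | lumenal flank |
|---|---|---|---|
| ER | 20 ± 2 | background + Met/Cys | acidic (D/E-rich) |
| Golgi | 19 ± 2 | large residues (F .24, L .34, I .18, W) | serine-rich linker |
| TGN/endosomes | 22 ± 2 | β-branched (I .26, V .28), mildly small | amide-rich |
| PM | 26 ± 2 | small residues (V .28, G, A, S, C) | mixed |

Core lengths are discrete uniform on mean ± 2. All inner halves perturb a
shared L/I/V/F/A-rich hydrophobic background; the PM inner half is
additionally Leu/Phe-enriched (the large-inner/small-outer signature).
Cytosolic flanks are K/R-enriched (positive-inside) with charge density
rising ER → Golgi → TGN → PM. These orderings reproduce the qualitative
headline patterns — length gradient, outer-leaflet volume bifurcation,
leaflet-preference sign pattern, ≥70% four-class cross-validation accuracy
— and are frozen; they are emulation parameters, not measurements.

Flank models split into a 2-residue uncharged *interface* pool adjacent to
the core and a *bulk* pool beyond it. At generation time the three residues
spanning each core boundary are redrawn until the 5-residue window centered
on the last core residue passes the GES rule and the window one step out
fails (`_sharpen_edge`). This conditioning makes the generative core
interval *operationally true* — the hydrophobic stretch really ends where
the label says — which is what makes edge-recovery a well-posed target
(≥95% of clean draws recovered within ±1 residue). The cost is a slight
hydrophilic tilt of interface-position composition relative to the raw
pools.

A neutral `calibration_preset()` (background composition both halves,
lengths uniform 16–30) isolates scanner properties from organelle biases;
cross-scale length rank correlations (> 0.9 in practice, asserted > 0.7)
are evaluated there.

What the generator does *not* emulate: phylogenetic correlation among
orthologs, realistic marginal residue usage outside the TMD neighbourhood,
sequence families other than the explicit near-duplicate constructor, and
signal peptides. Passing tests therefore demonstrate that the machinery
measures what it claims on data with the assumed structure — not that real
proteomes carry these exact effect sizes.

Problem sizes: organelle sets of n = 99 per class (four classes) for all
classifier work; 150–200 draws per preset for recovery and correlation
checks; 1000 draws for frequency-recovery tolerance (±0.05, binomial).
These sizes give the assertions comfortable statistical margins while the
whole suite runs in well under a minute.

## Known limitations

* Edge placement inherits the centered-window biases described above; on
  real proteins with gradual hydrophobicity boundaries, scanned lengths are
  systematically conservative near charged flanks.
* The Wimley–White scanner refuses small-residue-rich cores; analyses under
  that scale cover the scannable subset only.
* Identity scoring is not the original clustering tool's; only the 30%
  threshold semantics are preserved.
* The classifier is deliberately tiny and its accuracy on the synthetic
  presets reflects the presets' built-in separability; it is a faithful
  reimplementation of the method, not a state-of-the-art predictor.
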