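# GES hydrophobicity scale (Engelman, Steitz & Goldman 1986), kcal/mol.
# Sign convention used throughout this package: NEGATIVE = bilayer-preferring
# (hydrophobic). The published GES transfer free energies are positive for
# hydrophobic residues; the values below are the published table multiplied
# by -1 so that all three embedded scales share the same orientation.
# Columns: residue, value (kcal/mol, sign-adjusted).
residue	value
A	-1.6
R	12.3
N	4.8
D	9.2
C	-2.0
Q	4.1
E	8.2
G	-1.0
H	3.0
I	-3.1
L	-2.8
K	8.8
M	-3.4
F	-3.7
P	0.2
S	-0.6
T	-1.2
W	-1.9
Y	0.7
V	-2.6
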