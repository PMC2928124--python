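# Wimley-White water-to-octanol transfer free energies (Wimley, Creamer &
# White 1996), kcal/mol. Published orientation already has hydrophobic
# residues negative; no sign flip applied. Charged-residue values are for
# the ionized side chains. The octanol variant (not the interface scale) is
# the one whose two most hydrophilic residues are D (3.64) and E (3.63),
# matching the 3.60 kcal/mol individual-residue edge threshold used here.
# Columns: residue, value (kcal/mol).
residue	value
A	0.50
R	1.81
N	0.85
D	3.64
C	-0.02
Q	0.77
E	3.63
G	1.15
H	2.33
I	-1.12
L	-1.25
K	2.80
M	-0.67
F	-1.71
P	0.14
S	0.46
T	0.25
W	-2.09
Y	-0.71
V	-0.46
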