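residue	charge	polarity	hydropathy	size_class
A	neutral	nonpolar	hydrophobic	tiny
R	positive	polar	hydrophilic	large
N	neutral	polar	hydrophilic	small
D	negative	polar	hydrophilic	small
C	neutral	polar	hydrophobic	small
Q	neutral	polar	hydrophilic	medium
E	negative	polar	hydrophilic	medium
G	neutral	nonpolar	neutral	tiny
H	positive	polar	hydrophilic	medium
I	neutral	nonpolar	hydrophobic	large
L	neutral	nonpolar	hydrophobic	large
K	positive	polar	hydrophilic	large
M	neutral	nonpolar	hydrophobic	large
F	neutral	nonpolar	hydrophobic	large
P	neutral	nonpolar	hydrophilic	small
S	neutral	polar	neutral	tiny
T	neutral	polar	neutral	small
W	neutral	nonpolar	neutral	large
Y	neutral	polar	hydrophilic	large
V	neutral	nonpolar	hydrophobic	medium
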