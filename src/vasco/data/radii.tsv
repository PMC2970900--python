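# van der Waals radii (Angstrom), Chothia-style element set, version 1
element	radius
C	1.87
N	1.65
O	1.40
S	1.85
H	1.00
P	1.90
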