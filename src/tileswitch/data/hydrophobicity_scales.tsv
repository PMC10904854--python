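# Per-residue hydrophobicity scales.
# miyazawa: Miyazawa & Jernigan (1985) contact-energy-derived hydrophobicity.
# kyte_doolittle: Kyte & Doolittle (1982) hydropathy index.
residue	miyazawa	kyte_doolittle
A	5.33	1.8
R	4.18	-4.5
N	3.71	-3.5
D	3.59	-3.5
C	7.93	2.5
Q	3.87	-3.5
E	3.65	-3.5
G	4.48	-0.4
H	5.10	-3.2
I	8.83	4.5
L	8.47	3.8
K	2.95	-3.9
M	8.95	1.9
F	9.03	2.8
P	3.87	-1.6
S	4.09	-0.8
T	4.49	-0.7
W	7.66	-0.9
Y	5.89	-1.3
V	7.63	4.2
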