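# Default one-bead-per-residue parameter table (atom CA carries the whole
# residue: average residue mass, net formal charge at pH 7).
# LIG/PRB rows cover pseudo-ligand and probe beads from the generators.
residue_name	atom_name	mass	charge	lj_epsilon	lj_rmin_half	gb_radius
ALA	CA	71.0788	0.0000	0.1000	2.6000	3.0000
ARG	CA	156.1875	1.0000	0.1000	2.6000	3.0000
ASN	CA	114.1038	0.0000	0.1000	2.6000	3.0000
ASP	CA	115.0886	-1.0000	0.1000	2.6000	3.0000
CYS	CA	103.1388	0.0000	0.1000	2.6000	3.0000
GLN	CA	128.1307	0.0000	0.1000	2.6000	3.0000
GLU	CA	129.1155	-1.0000	0.1000	2.6000	3.0000
GLY	CA	57.0519	0.0000	0.1000	2.6000	3.0000
HIS	CA	137.1411	0.0000	0.1000	2.6000	3.0000
ILE	CA	113.1594	0.0000	0.1000	2.6000	3.0000
LEU	CA	113.1594	0.0000	0.1000	2.6000	3.0000
LYS	CA	128.1741	1.0000	0.1000	2.6000	3.0000
MET	CA	131.1926	0.0000	0.1000	2.6000	3.0000
PHE	CA	147.1766	0.0000	0.1000	2.6000	3.0000
PRO	CA	97.1167	0.0000	0.1000	2.6000	3.0000
SER	CA	87.0782	0.0000	0.1000	2.6000	3.0000
THR	CA	101.1051	0.0000	0.1000	2.6000	3.0000
TRP	CA	186.2132	0.0000	0.1000	2.6000	3.0000
TYR	CA	163.1760	0.0000	0.1000	2.6000	3.0000
VAL	CA	99.1326	0.0000	0.1000	2.6000	3.0000
LIG	C1	100.0000	0.0000	0.1200	2.0000	2.0000
LIG	C2	100.0000	0.0000	0.1200	2.0000	2.0000
LIG	C3	100.0000	0.0000	0.1200	2.0000	2.0000
LIG	C4	100.0000	0.0000	0.1200	2.0000	2.0000
LIG	C5	100.0000	0.0000	0.1200	2.0000	2.0000
LIG	C6	100.0000	0.0000	0.1200	2.0000	2.0000
PRB	C1	78.1100	0.0000	0.1200	2.6000	2.6000
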