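# Minimal heavy-atom table: backbone N/CA/C/O (+CB except GLY) for the 20
# standard residues, with generic backbone charges and mbondi-style GB radii.
residue_name	atom_name	mass	charge	lj_epsilon	lj_rmin_half	gb_radius
ALA	N	14.0067	-0.4157	0.1700	1.8240	1.5500
ALA	CA	12.0110	0.0337	0.1094	1.9080	1.7000
ALA	C	12.0110	0.5973	0.0860	1.9080	1.7000
ALA	O	15.9994	-0.5679	0.2100	1.6612	1.5000
ALA	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
ARG	N	14.0067	-0.4157	0.1700	1.8240	1.5500
ARG	CA	12.0110	0.0337	0.1094	1.9080	1.7000
ARG	C	12.0110	0.5973	0.0860	1.9080	1.7000
ARG	O	15.9994	-0.5679	0.2100	1.6612	1.5000
ARG	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
ASN	N	14.0067	-0.4157	0.1700	1.8240	1.5500
ASN	CA	12.0110	0.0337	0.1094	1.9080	1.7000
ASN	C	12.0110	0.5973	0.0860	1.9080	1.7000
ASN	O	15.9994	-0.5679	0.2100	1.6612	1.5000
ASN	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
ASP	N	14.0067	-0.4157	0.1700	1.8240	1.5500
ASP	CA	12.0110	0.0337	0.1094	1.9080	1.7000
ASP	C	12.0110	0.5973	0.0860	1.9080	1.7000
ASP	O	15.9994	-0.5679	0.2100	1.6612	1.5000
ASP	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
CYS	N	14.0067	-0.4157	0.1700	1.8240	1.5500
CYS	CA	12.0110	0.0337	0.1094	1.9080	1.7000
CYS	C	12.0110	0.5973	0.0860	1.9080	1.7000
CYS	O	15.9994	-0.5679	0.2100	1.6612	1.5000
CYS	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
GLN	N	14.0067	-0.4157	0.1700	1.8240	1.5500
GLN	CA	12.0110	0.0337	0.1094	1.9080	1.7000
GLN	C	12.0110	0.5973	0.0860	1.9080	1.7000
GLN	O	15.9994	-0.5679	0.2100	1.6612	1.5000
GLN	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
GLU	N	14.0067	-0.4157	0.1700	1.8240	1.5500
GLU	CA	12.0110	0.0337	0.1094	1.9080	1.7000
GLU	C	12.0110	0.5973	0.0860	1.9080	1.7000
GLU	O	15.9994	-0.5679	0.2100	1.6612	1.5000
GLU	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
GLY	N	14.0067	-0.4157	0.1700	1.8240	1.5500
GLY	CA	12.0110	0.0337	0.1094	1.9080	1.7000
GLY	C	12.0110	0.5973	0.0860	1.9080	1.7000
GLY	O	15.9994	-0.5679	0.2100	1.6612	1.5000
HIS	N	14.0067	-0.4157	0.1700	1.8240	1.5500
HIS	CA	12.0110	0.0337	0.1094	1.9080	1.7000
HIS	C	12.0110	0.5973	0.0860	1.9080	1.7000
HIS	O	15.9994	-0.5679	0.2100	1.6612	1.5000
HIS	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
ILE	N	14.0067	-0.4157	0.1700	1.8240	1.5500
ILE	CA	12.0110	0.0337	0.1094	1.9080	1.7000
ILE	C	12.0110	0.5973	0.0860	1.9080	1.7000
ILE	O	15.9994	-0.5679	0.2100	1.6612	1.5000
ILE	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
LEU	N	14.0067	-0.4157	0.1700	1.8240	1.5500
LEU	CA	12.0110	0.0337	0.1094	1.9080	1.7000
LEU	C	12.0110	0.5973	0.0860	1.9080	1.7000
LEU	O	15.9994	-0.5679	0.2100	1.6612	1.5000
LEU	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
LYS	N	14.0067	-0.4157	0.1700	1.8240	1.5500
LYS	CA	12.0110	0.0337	0.1094	1.9080	1.7000
LYS	C	12.0110	0.5973	0.0860	1.9080	1.7000
LYS	O	15.9994	-0.5679	0.2100	1.6612	1.5000
LYS	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
MET	N	14.0067	-0.4157	0.1700	1.8240	1.5500
MET	CA	12.0110	0.0337	0.1094	1.9080	1.7000
MET	C	12.0110	0.5973	0.0860	1.9080	1.7000
MET	O	15.9994	-0.5679	0.2100	1.6612	1.5000
MET	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
PHE	N	14.0067	-0.4157	0.1700	1.8240	1.5500
PHE	CA	12.0110	0.0337	0.1094	1.9080	1.7000
PHE	C	12.0110	0.5973	0.0860	1.9080	1.7000
PHE	O	15.9994	-0.5679	0.2100	1.6612	1.5000
PHE	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
PRO	N	14.0067	-0.4157	0.1700	1.8240	1.5500
PRO	CA	12.0110	0.0337	0.1094	1.9080	1.7000
PRO	C	12.0110	0.5973	0.0860	1.9080	1.7000
PRO	O	15.9994	-0.5679	0.2100	1.6612	1.5000
PRO	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
SER	N	14.0067	-0.4157	0.1700	1.8240	1.5500
SER	CA	12.0110	0.0337	0.1094	1.9080	1.7000
SER	C	12.0110	0.5973	0.0860	1.9080	1.7000
SER	O	15.9994	-0.5679	0.2100	1.6612	1.5000
SER	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
THR	N	14.0067	-0.4157	0.1700	1.8240	1.5500
THR	CA	12.0110	0.0337	0.1094	1.9080	1.7000
THR	C	12.0110	0.5973	0.0860	1.9080	1.7000
THR	O	15.9994	-0.5679	0.2100	1.6612	1.5000
THR	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
TRP	N	14.0067	-0.4157	0.1700	1.8240	1.5500
TRP	CA	12.0110	0.0337	0.1094	1.9080	1.7000
TRP	C	12.0110	0.5973	0.0860	1.9080	1.7000
TRP	O	15.9994	-0.5679	0.2100	1.6612	1.5000
TRP	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
TYR	N	14.0067	-0.4157	0.1700	1.8240	1.5500
TYR	CA	12.0110	0.0337	0.1094	1.9080	1.7000
TYR	C	12.0110	0.5973	0.0860	1.9080	1.7000
TYR	O	15.9994	-0.5679	0.2100	1.6612	1.5000
TYR	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
VAL	N	14.0067	-0.4157	0.1700	1.8240	1.5500
VAL	CA	12.0110	0.0337	0.1094	1.9080	1.7000
VAL	C	12.0110	0.5973	0.0860	1.9080	1.7000
VAL	O	15.9994	-0.5679	0.2100	1.6612	1.5000
VAL	CB	12.0110	-0.1825	0.1094	1.9080	1.7000
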