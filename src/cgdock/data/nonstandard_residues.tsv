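# Non-standard residue name -> standard counterpart.
# Editable: one tab-separated pair per line.
MSE	MET
SEC	CYS
PYL	LYS
SEP	SER
TPO	THR
PTR	TYR
CSO	CYS
CSD	CYS
CSX	CYS
CME	CYS
OCS	CYS
KCX	LYS
MLY	LYS
M3L	LYS
ALY	LYS
LLP	LYS
HYP	PRO
FME	MET
MLE	LEU
HIC	HIS
NEP	HIS
PCA	GLU
CGU	GLU
AIB	ALA
DAL	ALA
SAR	GLY
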