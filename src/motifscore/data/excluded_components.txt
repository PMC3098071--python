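# Solvent and crystallization additives never treated as the ligand and
# dropped from complexes on loading (unless explicitly designated as the
# ligand of interest).  One component id per line.
HOH
WAT
DOD
CL
BR
IOD
F
NA
K
NH4
SO4
PO4
NO3
CO3
ACT
GOL
EDO
PEG
PG4
MPD
DMS
BME
FMT
TRS
EPE
MES
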