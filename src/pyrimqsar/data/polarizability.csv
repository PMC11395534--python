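# Static atomic dipole polarizabilities (Angstrom^3), CRC-style table as
# used by the classic 2D-autocorrelation descriptor software (note the
# carbon value 1.67 of that lineage rather than the newer 1.76).
# table_version=autocorr-classic
element,value
H,0.666793
C,1.67
N,1.10
O,0.802
F,0.557
P,3.63
S,2.90
Cl,2.18
Br,3.05
I,5.35
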