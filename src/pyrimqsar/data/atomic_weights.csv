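# Conventional atomic weights (g/mol), IUPAC 2005 conventional values.
# Versioned constant: table_version=2005-conventional. These reproduce the
# two-decimal molecular weights conventionally printed for small organics
# (e.g. C7H9IN2O2 -> 280.06).
element,weight
H,1.00794
C,12.0107
N,14.0067
O,15.9994
F,18.9984032
P,30.973762
S,32.065
Cl,35.453
Br,79.904
I,126.90447
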