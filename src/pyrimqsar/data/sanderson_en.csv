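# Sanderson electronegativities (dimensionless), Sanderson 1983 scale as
# tabulated in standard molecular-descriptor references.
# table_version=sanderson-1983
element,value
H,2.592
C,2.746
N,3.194
O,3.654
F,4.000
P,2.515
S,2.957
Cl,3.475
Br,3.219
I,2.778
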