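O=c1[nH]cc(CCCI)c(=O)[nH]1 cpd40_5-(3-iodopropyl)pyrimidine-2,4-dione
ClCCCc1cnc(Cl)nc1Cl cpd41_5-(3-chloropropyl)-2,4-dichloropyrimidine
Clc1ncc2c(n1)OCCC2 cpd42_2-chloro-6,7-dihydro-5H-pyrano[2,3-d]pyrimidine
COc1ncc(CCCCl)c(OC)n1 cpd43_5-(3-chloropropyl)-2,4-dimethoxypyrimidine
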