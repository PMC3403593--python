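Ar
Bcl6
Brca1
Etv4
Fus
Gli1
Hes1
Hnf1b
Hnrnpk
Klf10
Klf4
Lyl1
Mef2c
Nfia
Nr2f1
Nrl
Pax6
Sp2
Sp4
Tcfap2b
Wt1
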