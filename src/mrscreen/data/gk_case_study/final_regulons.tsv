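tf	gene
Etv4	Mcm10
Etv4	Erbb2
Etv4	Mmp7
Etv4	Nid1
Etv4	Plau
Etv4	Ptgs2
Fus	Mcpt8l2
Fus	Mcpt9
Fus	Paics
Fus	Ppat
Fus	Ugt1a1
Fus	Ugt1a2
Fus	Ugt1a3
Fus	Ugt1a5
Fus	Ugt1a6
Fus	Ugt1a7c
Fus	Ugt1a8
Fus	Ugt1a9
Nr2f1	Alox5
Nr2f1	Cpt1b
Nr2f1	Cyp11b2
Nr2f1	Tf
Nr2f1	Ugt1a3
Nr2f1	Ugt1a5
Sp2	Capns1
Sp2	Irs2
Sp2	LOC685183
Sp2	LOC685226
Sp2	LOC685291
Sp2	LOC685759
Sp2	LOC688519
Sp2	LOC688603
Sp2	LOC689083
Sp2	LOC689312
Sp2	LOC689338
Sp2	LOC689690
Sp2	LOC689999
Sp2	LOC690179
Sp2	LOC690328
Sp2	LOC690379
Sp2	LOC690577
Sp2	LOC691712
Sp2	LOC691735
Sp2	LOC691754
Sp2	Papss2
Sp2	Vom2r45
Sp2	Vom2r46
Sp2	Vom2r47
Tcfap2b	Aqp1
Tcfap2b	Egfr
Tcfap2b	Krt14
Tcfap2b	Ptgds
Tcfap2b	Sod2
Tcfap2b	Tgm1
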