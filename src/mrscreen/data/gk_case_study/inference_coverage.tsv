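strain	period	tf	n_regulated
case	P1	Arntl	31
case	P1	Lhx2	22
case	P1	Sp2	18
case	P1	Gabpa	13
case	P1	Xpa	4
case	P1	Foxs1	3
control	P1	Max	10
control	P1	Otx2	10
control	P1	Daxx	9
control	P1	Sim1	9
control	P1	Tcf21	8
control	P1	Gata5	7
control	P1	Tcfap2c	7
control	P1	Meis3	5
control	P1	Rorc	5
control	P1	Snapc1	5
control	P1	Zic2	5
control	P1	Meis1	4
control	P1	Pou2af1	4
control	P1	Srf	4
control	P1	Stox2	4
control	P1	Tcfcp2l1	4
control	P1	Gtf2h2	3
control	P1	Zfx	3
case	P2	Lhx5	24
case	P2	Etv1	23
case	P2	Ctnnb1	8
case	P2	Rpa3	8
case	P2	Zfp105	8
case	P2	Foxo3	7
case	P2	Hoxc5	6
case	P2	Litaf	6
case	P2	Nr2f2	6
case	P2	Foxo1	5
case	P2	Msx1	5
case	P2	Myocd	5
case	P2	Pbx1	5
case	P2	Tbpl1	5
case	P2	Vdr	5
case	P2	Hltf	4
case	P2	Htt	4
case	P2	LOC680117	4
case	P2	Mbd1	4
case	P2	Parp1	4
case	P2	Rreb1	4
case	P2	Smarcc1	4
control	P2	Ywhae	18
control	P2	Pfdn5	13
control	P2	Atf1	11
control	P2	Cdk9	11
control	P2	Hmgb2	11
control	P2	Sfpq	9
control	P2	Zfp281	9
control	P2	Cdk7	8
control	P2	Ets2	8
control	P2	Hoxa1	8
control	P2	Nfe2l2	8
control	P2	Nfil3	8
control	P2	Six4	8
control	P2	Cux2	7
control	P2	Mafg	7
control	P2	Nfkbia	7
control	P2	Pgr	7
control	P2	Ppp1r13b	7
control	P2	Tbpl1	7
control	P2	Cbfb	6
control	P2	Ezh2	6
control	P2	Hbp1	6
control	P2	Junb	6
control	P2	Taf13	6
control	P2	Tef	6
case	P3	Fus	10
case	P3	Smad5	10
case	P3	Nfx1	9
case	P3	Hsf1	8
case	P3	Tlx3	8
case	P3	Tp53	8
case	P3	Foxs1	7
case	P3	LOC679869	7
case	P3	Cbfb	6
case	P3	Ctcf	6
case	P3	Glis2	6
case	P3	Irf7	6
case	P3	Nfkbib	6
case	P3	Nr1i2	6
case	P3	Hdac1	5
case	P3	Rfx5	5
case	P3	Tle1	5
case	P3	Xpa	5
control	P3	Foxq1	32
control	P3	Hoxa1	16
control	P3	Rbl2	16
control	P3	Zic2	12
control	P3	Rorc	8
control	P3	Tcfap4	6
control	P3	Pttg1	5
control	P3	Ncoa3	4
control	P3	Ccnh	3
control	P3	Hif1a	3
control	P3	Junb	3
control	P3	Kcnip1	3
control	P3	Mtf1	3
control	P3	Zfp148	3
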