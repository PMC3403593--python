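Alx1
Arnt
Cebpg
Ddit3
Dlx5
Dmrt2
Dnmt1
Dr1
Ebf1
Elf5
Elk3
Elk4
Erg
Etv4
Etv5
Fev
Fosl1
Foxe1
Foxg1
Foxo3
Foxp4
Gabpb1l
Gfi1
Gtf2a1
Gtf2b
Gtf2e1
Gzf1
Hcfc1
Hey1
Hhex
Hoxb3
Hoxb7
Ilf3
Irx2
Kcnip4
Klf1
Klf15
Klf3
Klf5
Klf7
Ldb2
LOC680117
Mafk
Meis2
Mnat1
Msx1
Msx2
Mybl2
Myc
Myocd
Myod1
Mzf1
Neurod2
Nfix
Nfx1
Nkx6-1
Notch1
Nr1h4
Nr2f1
Nr4a1
Nr5a1
Pax8
Pbx2
Phox2a
Pitx1
Pitx3
Pou2f3
Pou3f1
Ppard
Pparg
Ppargc1a
Rbl1
RGD1566107
Rreb1
Runx1
Shh
Six5
Six6
Skp2
Sox10
Sox11
Sp1
Sp2
Spdef
Srebf1
Ss18l1
Stat5a
Stat5b
Taf2
Tbx18
Tbx2
Tcf12
Tcfap2b
Tead1
Tfdp2
Tfec
Tmf1
Tp53bp1
Twist1
Vdr
Zbtb5
Zfhx3
Zfp191
Zfp238
Zfp423
Zfp444
Zhx1
Zic1
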