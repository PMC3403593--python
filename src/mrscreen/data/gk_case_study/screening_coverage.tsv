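strain	period	tf	n_regulated
case	P1	SP1	10
control	P1	SP1	19
control	P1	SP3	8
control	P1	TP53	4
case	P2	SP1	39
case	P2	SP3	11
case	P2	TP53	11
case	P2	EGR1	6
case	P2	NRF1	6
case	P2	TCFAP2A	5
control	P2	SP1	18
control	P2	HNF4A	6
control	P2	FOXO3	4
case	P3	SP1	12
case	P3	SP3	3
control	P3	SP1	5
control	P3	FOXO3	3
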