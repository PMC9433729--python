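gene_symbol	hgvs_c	hgvs_p	consequence	n_participants
CHEK2	c.1229del	p.Thr410MetfsTer15	frameshift	16
CHEK2	c.1392del	p.Ser465ValfsTer15	frameshift	4
CHEK2	c.478A>G	p.Arg160Gly	missense	2
CHEK2	c.573+1G>A	.	splice_disruption	2
CHEK2	c.1031del	p.Leu344TrpfsTer3	frameshift	1
CHEK2	c.720del	p.Val241PhefsTer7	frameshift	1
MITF	c.1273G>A	p.Glu318Lys	missense	10
SDHA	c.91C>T	p.Arg31Ter	stop_gained	7
VHL	c.227_229del	p.Phe76del	inframe_indel	1
VHL	c.233A>G	p.Asn78Ser	missense	1
VHL	c.461C>T	p.Pro154Leu	missense	1
VHL	c.286C>T	p.Gln96Ter	stop_gained	1
VHL	c.551T>C	p.Leu184Pro	missense	1
FLCN	c.33C>A	p.Cys11Ter	stop_gained	1
FLCN	c.490del	p.Arg164GlyfsTer13	frameshift	1
FLCN	c.890_893del	p.Glu297AlafsTer25	frameshift	1
FLCN	c.853C>T	p.Gln285Ter	stop_gained	1
FH	c.1127A>C	p.Gln376Pro	missense	1
FH	c.431G>T	p.Gly144Val	missense	1
FH	c.413_414del	p.Leu138ArgfsTer17	frameshift	1
SDHB	c.72+1G>T	.	splice_disruption	1
SDHB	c.600G>T	p.Trp200Cys	missense	1
ATM	c.1339C>T	p.Arg447Ter	stop_gained	2
ATM	c.964_968del	p.Glu322LysfsTer6	frameshift	1
ATM	c.1442T>G	p.Leu481Ter	stop_gained	1
ATM	c.1782del	p.Val595CysfsTer19	frameshift	1
ATM	c.2466+1G>A	.	splice_disruption	1
ATM	c.3451A>T	p.Lys1151Ter	stop_gained	1
ATM	c.8147T>C	p.Val2716Ala	missense	1
ATM	c.652C>T	p.Gln218Ter	stop_gained	1
ATM	c.742C>T	p.Arg248Ter	stop_gained	1
FANCM	c.5101C>T	p.Gln1701Ter	stop_gained	2
FANCM	c.1972C>T	p.Arg658Ter	stop_gained	1
FANCM	c.3235_3238del	p.Leu1080ValfsTer14	frameshift	1
BRIP1	c.3401del	p.Pro1134LeufsTer16	frameshift	1
BRIP1	c.2992_2995del	p.Lys998GlufsTer60	frameshift	1
BRIP1	c.2392C>T	p.Arg798Ter	stop_gained	1
MSH6	c.3261del	p.Phe1088SerfsTer2	frameshift	1
MSH6	c.3259_3260insT	p.Pro1087LeufsTer6	frameshift	1
MSH6	c.3562_3563del	p.Ser1188TyrfsTer5	frameshift	1
BRCA2	c.9253dup	p.Thr3085AsnfsTer26	frameshift	1
BRCA2	c.4876_4877del	p.Asn1626SerfsTer12	frameshift	1
PMS2	c.1A>G	p.Met1?	start_lost	1
PMS2	c.1778del	p.Lys593SerfsTer2	frameshift	1
TP53	c.655C>T	p.Pro219Ser	missense	1
TP53	c.586C>T	p.Arg196Ter	stop_gained	1
MSH2	c.942_942+2del	p.Val265_Gln314del	splice_disruption	1
PALB2	c.3113G>A	p.Trp1038Ter	stop_gained	1
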