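gene	direction
A2M	up
ADAMTS1	up
ADAMTS4	up
ADAMTS9	up
ADAMTSL4	up
ANGPTL4	up
ANPEP	up
ANXA2	up
APOE	up
APOLD1	up
AQP1	up
ARID5A	up
B2M	up
BCL3	up
BCL6	up
BHLHE40	up
BTG2	up
C10orf10	up
C11orf96	up
C1QTNF1	up
C1RL	up
C1S	up
C3	up
CASP4	up
CCNL1	up
CD14	up
CD59	up
CD63	up
CDK2	up
CEBPB	up
CEBPD	up
CFB	up
CHSY1	up
CLEC3B	up
CREM	up
CRISPLD2	up
CSF1	up
CSRNP1	up
CTSB	up
CTSL	up
CTSZ	up
DDR1	up
DEC1	up
DUSP1	up
DUSP5	up
EGFL7	up
EGR1	up
EIF4A1	up
EMP1	up
ETS2	up
F3	up
FOS	up
FOSL1	up
FOSL2	up
GADD45A	up
GADD45B	up
GLIPR1	up
GPR4	up
HAPLN3	up
HILPDA	up
ICAM1	up
IER2	up
IER3	up
IFI16	up
IGFBP2	up
IGFBP3	up
IGFBP4	up
IGFBP7	up
IL1R1	up
IL4R	up
IL6	up
INHBB	up
ITPKC	up
ITPRIP	up
JUN	up
JUNB	up
KIAA0040	up
KLF10	up
KLF6	up
KRT15	up
KRT18	up
LAMA5	up
LGALS3	up
LMNB1	down
LOX	up
LTBP1	up
MAFF	up
MAN2B1	up
MAPK11	up
MCL1	up
MIDN	up
MOV10	up
MT1A	up
MT1M	up
MT1X	up
MYC	up
NAMPT	up
NEDD9	up
NFIL3	up
NFKB2	up
NFKBIZ	up
NR4A1	up
NUCB1	up
NXT1	up
OSMR	up
PDGFB	up
PDLIM1	up
PIM1	up
PLAUR	up
PLK3	up
PLSCR1	up
PLTP	up
PNP	up
PNRC1	up
PPP1R18	up
PPRC1	up
PROS1	up
RASD1	up
RGS16	up
RNASET2	up
RND3	up
RNF122	up
RPS3	up
SAT1	up
SBNO2	up
SEMA3F	up
SEMA4B	up
SERPINB1	up
SERPINE1	up
SERPING1	up
SERTAD1	up
SFN	up
SHC1	up
SLC25A25	up
SLC2A3	up
SLC39A1	up
SLC39A14	up
SLCO4A1	up
SNAI1	up
SNRPC	up
SOCS3	up
SOD2	up
STAT3	up
STC1	up
SUSD6	up
TGFBI	up
TGIF1	up
THBD	up
THBS1	up
TIMP1	up
TIMP3	up
TNFRSF10B	up
TNFRSF10D	up
TNFRSF12A	up
TNFRSF1A	up
TP53	up
TRIB1	up
TSKU	up
UBC	up
VCAM1	up
VEGFA	up
VEGFC	up
YBX3	up
ZC3H12A	up
ZFP36	up
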