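symbol	tier	cmp_class	category	inheritance	pli	heart_expression
MYH7	1	primary	sarcomere	AD	0.99	high
MYBPC3	1	primary	sarcomere	AD	0.0	high
TNNT2	1	primary	sarcomere	AD	0.84	high
TNNI3	1	primary	sarcomere	AD	0.02	high
TPM1	1	primary	sarcomere	AD	0.91	high
ACTC1	1	primary	sarcomere	AD	0.72	high
MYL2	1	primary	sarcomere	AD	0.03	high
MYL3	1	primary	sarcomere	AD	0.27	high
MYH6	1	primary	sarcomere	AD	0.0	high
DSP	1	primary	desmosomal	AD	1.0	high
PKP2	1	primary	desmosomal	AD	0.0	high
DSG2	1	primary	desmosomal	AD	0.0	high
DSC2	1	primary	desmosomal	AD	0.0	high
JUP	1	primary	desmosomal	AD	0.11	high
CTNNA3	2	primary	desmosomal	AD	0.0	high
FKTN	2	primary	dystroglycan	AR	0.0	moderate
FKRP	2	primary	dystroglycan	AR	0.0	moderate
DAG1	2	primary	dystroglycan	AR	0.0	moderate
POMGNT1	2	primary	dystroglycan	AR	0.0	moderate
DTNA	2	primary	dystroglycan	AD	0.0	moderate
SCN5A	2	primary	ion_channel	AD	1.0	high
RYR2	2	primary	ion_channel	AD	1.0	high
HCN4	2	primary	ion_channel	AD	0.95	high
CACNA1C	2	primary	ion_channel	AD	1.0	high
KCNQ1	2	primary	ion_channel	AD	0.28	high
KCNH2	2	primary	ion_channel	AD	0.98	high
ABCC9	2	primary	ion_channel	AD	0.0	high
CASQ2	2	primary	ion_channel	AD	0.0	high
DES	1	primary	cytoskeletal	AD	0.0	high
FLNC	1	primary	cytoskeletal	AD	1.0	high
ACTN2	1	primary	cytoskeletal	AD	0.99	high
LDB3	2	primary	cytoskeletal	AD	0.0	high
MYPN	2	primary	cytoskeletal	AD	0.0	high
NEBL	2	primary	cytoskeletal	AD	0.0	high
VCL	2	primary	cytoskeletal	AD	1.0	high
ANKRD1	2	primary	cytoskeletal	AD	0.0	high
CSRP3	1	primary	cytoskeletal	AD	0.07	high
TTN	1	primary	cytoskeletal	AD	0.0	high
DMD	1	primary	cytoskeletal	XL	1.0	high
SGCD	2	primary	cytoskeletal	AR	0.0	high
ILK	2	primary	cytoskeletal	AD	0.0	high
MYOZ2	2	primary	cytoskeletal	AD	0.0	high
TCAP	2	primary	cytoskeletal	AR	0.09	high
PDLIM3	2	primary	cytoskeletal	AD	0.0	high
SYNM	2	primary	cytoskeletal	AD	0.0	high
LAMA4	2	primary	cytoskeletal	AD	0.0	high
LMNA	1	primary	other	AD	0.99	high
EMD	1	primary	other	XL	0.08	high
TMEM43	1	primary	other	AD	0.0	high
PLN	1	primary	other	AD	0.57	high
JPH2	1	primary	other	AD	0.7	high
NEXN	2	primary	other	AD	0.0	high
RBM20	1	primary	other	AD	1.0	high
BAG3	1	primary	other	AD	0.9	high
TNNC1	1	primary	other	AD	0.38	high
CRYAB	2	primary	other	AD	0.12	high
PRKAG2	1	primary	other	AD	0.92	high
ALPK3	2	primary	other	AR	0.0	high
FHOD3	2	primary	other	AD	0.99	high
MYLK2	2	primary	other	AD	0.0	high
TRIM63	2	primary	other	AR	0.0	high
GATAD1	2	primary	other	AR	0.0	high
TBX20	2	primary	other	AD	0.95	high
NKX2-5	2	primary	other	AD	0.69	high
GATA4	2	primary	other	AD	0.99	high
GATA6	2	primary	other	AD	1.0	high
MIB1	2	primary	other	AD	1.0	high
PRDM16	2	primary	other	AD	1.0	high
HAND1	2	primary	other	AD	0.49	high
TGFB3	2	primary	other	AD	0.7	high
BRAF	2	secondary	other	AD	1.0	moderate
HRAS	2	secondary	other	AD	0.54	moderate
KRAS	2	secondary	other	AD	0.92	moderate
PTPN11	2	secondary	other	AD	1.0	moderate
RAF1	2	secondary	other	AD	1.0	moderate
SOS1	2	secondary	other	AD	1.0	moderate
MAP2K1	2	secondary	other	AD	0.99	moderate
GAA	2	secondary	other	AR	0.0	moderate
LAMP2	2	secondary	other	XL	0.51	moderate
GLA	2	secondary	other	XL	0.0	moderate
TAZ	2	secondary	other	XL	0.03	moderate
SGCA	2	secondary	other	AR	0.0	moderate
SGCB	2	secondary	other	AR	0.0	moderate
LAMA2	2	secondary	other	AR	0.0	moderate
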