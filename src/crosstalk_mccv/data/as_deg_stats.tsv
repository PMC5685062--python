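gene	log2fc	fdr
IL2RB	-1.055680	0.000366
GNG11	1.452149	0.000369
ADGRG1	-1.214451	0.000772
S100A12	1.438137	0.001421
KIR2DL3	-1.046953	0.001876
TMA7	1.121291	0.002057
CHMP5	1.014122	0.002439
PRF1	-1.018001	0.002573
LSM3	1.051145	0.003032
PPBP	1.233433	0.003703
UQCRB	1.154782	0.004073
COX7B	1.174587	0.005779
RPL23	1.071111	0.012291
MCEMP1	1.078964	0.012743
LY96	1.206473	0.022822
PTGDS	-1.115798	0.023302
COMMD6	1.108966	0.027617
RAP1GAP	1.336118	0.037313
DEFA4	1.013721	0.049562
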