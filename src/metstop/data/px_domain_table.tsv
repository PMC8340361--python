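name	ligands	lsi	mss	pss	mai	expression	structure	note
ARHGAP32	3,4,5	8	0	5	W	9.4	IT	
ARHGAP33	0	0	0	0	N	22.7	IT	
HS1BP3	3,34,35,45,345	5	2	0	S	8.4	IT	
KIF16B	3,34,45,345	6	0	1	S	6.2	2v14	
NISCH	3,34	8	0	6	W	83.0	3p0c	
NOXO1β	45,345	9	0	0	W	0.2	2l73	
NOXO1γ	4,5,35	7	0	2	W	0.1	IT	
p40phox	3	10	2	1	S	9.3	1h6h	
p47phox	3,34,45,345	6	1	6	S	25.9	1kq6	
PIK3C2α	34,35,45	8	2	1	S	19.0	2ar5	
PIK3C2β	34,45,345	8	0	2	S	9.7	IT	
PIK3C2γ	34,35,45,345	7	0	0	W	1.0	2wwe	
PLD1	345	10	0	1	S	5.4	IT	
PLD2	45	10	0	16	W	26.9	IT	
PXDC1	nd	nd	0	0	nd	69.6	IT	
PXK	3	10	0	4	W	18.9	IT	
RPS6KC1	3,34,45,345	6	0	6	S	9.9	IT	
SGK3	3,34	8	7	2	S	31.3	1xte	
SH3PXD2A	3	10	1	1	S	34.5	IT	
SH3PXD2B	3,34	8	3	6	S	19.3	IT	
SNX1	34	10	6	15	S	35.5	2i4k	
SNX2	34	10	13	17	S	43.9	IT	
SNX3	3	10	8	13	S	169.4	5f0j	
SNX4	3	10	0	3	W	22.0	IT	
SNX5	3,34,35,45	6	4	1	W	34.4	3hpc	
SNX6	4	10	9	2	W	29.4	IT	
SNX7	3	10	0	3	W	18.0	IT	
SNX8	3	10	3	0	S	11.0	IT	
SNX9	3,34,45,345	6	5	4	W	42.5	2raj	
SNX10	3	10	0	0	W	10.6	4on3	
SNX11	3,4,5,34,35,45,345	1	0	0	S	16.5	4ikb	
SNX12	3	10	2	8	S	41.3	2csk	
SNX13	3,34	8	0	3	W	7.9	IT	
SNX14	0	0	4	1	N	19.5	IT	
SNX15	3,4,34,35,45,345	3	3	0	S	26.9	IT	
SNX16	3	10	0	2	S	5.8	5gw0	
SNX17	3	10	0	9	S	89.3	IT	
SNX18	34,45	9	2	0	S	12.8	IT	
SNX19	3	10	0	2	S	26.4	IT	
SNX20	3,5,35,45	5	0	2	S	3.2	IT	
SNX21	3,45	8	0	6	S	32.1	IT	
SNX22	3,34,45,345	6	0	2	S	9.4	2ett	
SNX24	3,34,35,45	6	1	7	S	8.1	4az9	
SNX25	34,35,45,345	7	5	2	S	12.9	5woe	
SNX27	3	10	1	6	S	19.9	4has	
SNX29	3,34,45	7	2	0	S	8.0	IT	
SNX30	3	10	3	1	W	6.3	IT	lsi_inferred
SNX31	3	10	0	1	S	0.5	IT	
SNX32	0	0	2	3	N	4.9	6e8r	
SNX33	34,45	9	1	9	S	20.8	IT	lsi_inferred
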