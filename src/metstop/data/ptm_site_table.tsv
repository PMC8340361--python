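protein	species	residue	ptm_type	flank	study_count
HS1BP3	H. sapiens	K69	butyrylation	FLVSkKYSE	1
HS1BP3	H. sapiens	K70	butyrylation	LVSKkYSEI	1
p40phox	X. tropicalis	K92	acetylation	ELPPkIFVG	1
p40phox	M. musculus	K92	acetylation	TLPAkVYMG	1
p40phox	D. rerio	K92	acetylation	TLPGkVFMG	1
p40phox	B. taurus	K92	acetylation	TLPAkVYVG	1
p47phox	H. sapiens	K79	acetylation	LPAPkWFDG	1
PIK3C2A	H. sapiens	K1434	acetylation	FTYHkKYNP	1
PIK3C2A	H. sapiens	K1440	acetylation	YNPDkHYIY	1
SGK3	H. sapiens	K71	acetylation	AMALkIPAK	1
SGK3	M. musculus	K71	acetylation	AMALkIPAK	1
SGK3	M. musculus	K71	succinylation	AMALkIPAK	1
SGK3	H. sapiens	K75	acetylation	KIPAkRIFG	1
SGK3	H. sapiens	K75	methylation	KIPAkRIFG	1
SGK3	H. sapiens	K88	acetylation	PDFIkQRRA	1
SH3PXD2A	H. sapiens	K92	acetylation	DVAVkRLKP	1
SH3PXD2B	H. sapiens	K17	acetylation	LDVQkRRVP	1
SH3PXD2B	H. sapiens	K93	acetylation	DVAVkRLIP	1
SNX1	B. taurus	K184	acetylation	HFAVkRRFS	1
SNX1	B. taurus	K221	acetylation	IGMTkVKVG	1
SNX1	B. taurus	K226	acetylation	VKVGkEDSS	1
SNX1	H. sapiens	K237	acetylation	EFLEkRRAA	1
SNX1	R. norvegicus	K237	acetylation	EFLEkRRAA	1
SNX1	M. musculus	K237	acetylation	EFLEkRRAA	1
SNX1	C. elegans	K167	acetylation	SALTkTKTN	1
SNX1	D. rerio	K358	acetylation	MGMTkVKVG	1
SNX1	D. rerio	K363	acetylation	VKVGkEDPS	1
SNX2	H. sapiens	K181	acetylation	EFSVkRRFS	1
SNX2	M. musculus	K181	acetylation	EFSVkRRFS	1
SNX2	H. sapiens	K181	butyrylation	EFSVkRRFS	1
SNX2	H. sapiens	K211	malonylation	PAPEkSIVG	1
SNX2	H. sapiens	K211	acetylation	PAPEkSIVG	1
SNX2	H. sapiens	K218	acetylation	VGMTkVKVG	1
SNX2	H. sapiens	K223	acetylation	VKVGkEDSS	1
SNX2	H. sapiens	K234	acetylation	EFVEkRRAA	1
SNX2	H. sapiens	K234	succinylation	EFVEkRRAA	1
SNX3	S. pombe	R39	methylation	HGIGrNMFT	1
SNX3	H. sapiens	R43	methylation	VGVGrGRFT	1
SNX3	M. musculus	R43	methylation	VGVGrGRFT	1
SNX3	R. norvegicus	R43	methylation	VGVGrGRFT	1
SNX3	B. taurus	R43	methylation	VGVGrGRFT	1
SNX3	D. rerio	R43	methylation	VGVGrNRFT	1
SNX3	X. tropicalis	R43	methylation	IGVGrGRYT	1
SNX3	H. sapiens	R45	methylation	VGRGrFTTY	1
SNX3	M. musculus	R45	methylation	VGRGrFTTY	1
SNX3	R. norvegicus	R45	methylation	VGRGrFTTY	1
SNX3	B. taurus	R45	methylation	VGRGrFTTY	1
SNX3	C. elegans	R45	methylation	VGKMrYTDY	1
SNX3	D. rerio	R45	methylation	VGRNrFTTY	1
SNX3	X. tropicalis	R45	methylation	VGRGrYTTY	1
SNX3	M. musculus	R70	methylation	TVRRrYSDF	1
SNX5	H. sapiens	K46	acetylation	RDKVkFTVH	1
SNX5	H. sapiens	K108	acetylation	EKMQkLGEG	1
SNX5	H. sapiens	K118	acetylation	GSMTkEEFA	1
SNX6	H. sapiens	K47	acetylation	RDKVkFTVH	1
SNX6	H. sapiens	K109	acetylation	EKLQkLGEG	1
SNX6	H. sapiens	K119	acetylation	GSMTkEEFT	1
SNX6	H. sapiens	K124	acetylation	EEFTkMKQE	1
SNX8	H. sapiens	K85	acetylation	LIPEkKGLF	1
SNX8	H. sapiens	K91	acetylation	GLFLkHVEY	1
SNX9	H. sapiens	K267	methylation	MYGLkSYIE	1
SNX9	H. sapiens	K288	acetylation	NHRYkHFDW	1
SNX9	H. sapiens	K288	malonylation	NHRYkHFDW	1
SNX9	H. sapiens	K313	malonylation	SLPDkQVTG	1
SNX12	B. taurus	R44	methylation	VGVGrARFT	1
SNX12	B. taurus	R46	methylation	VGRArFTTY	1
SNX14	H. sapiens	K648	acetylation	IIGPkNYEF	1
SNX14	H. sapiens	K654	acetylation	YEFLkSKRE	1
SNX14	H. sapiens	K656	acetylation	FLKSkREEF	1
SNX15	M. musculus	R81	methylation	PAFPrAQVF	1
SNX18	H. sapiens	K314	malonylation	HRRYkHFDW	1
SNX18	H. sapiens	K338	malonylation	HLPEkQATG	1
SNX24	H. sapiens	K69	acetylation	NWVPkVLEQ	1
SNX25	H. sapiens	K584	acetylation	KLPFkSIDQ	1
SNX25	H. sapiens	K589	acetylation	SIDQkFMEK	1
SNX25	H. sapiens	K593	acetylation	KFMEkSKNQ	1
SNX27	H. sapiens	R218	methylation	FTFPrLPGK	1
SNX29	M. musculus	K729	acetylation	AIGNkDAKF	1
SNX30	D. rerio	K153	acetylation	KFVMkGVVD	1
SNX30	H. sapiens	K158	acetylation	PLPEkFVVK	1
SNX30	H. sapiens	K162	acetylation	KFVVkGVVD	1
SNX30	X. tropicalis	K171	acetylation	KFVVkGVVD	1
SNX32	H. sapiens	K100	glycation	ASREkLQKL	1
SNX32	H. sapiens	K103	glycation	EKLQkLGEG	1
SNX33	X. tropicalis	K243	acetylation	YRRYkHFDW	1
SNX33	D. rerio	K245	acetylation	YRRYkHFDW	1
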