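!gaf-version: 2.2
! hand-written mini fixture: six genes, six terms
MINI	gMPZ	gMPZ	involved_in	MINI:0000002	MINI:fixture	IDA		P			protein	taxon:32630	20240101	MINI
MINI	gPMP22	gPMP22	involved_in	MINI:0000002	MINI:fixture	IDA		P			protein	taxon:32630	20240101	MINI
MINI	gPRX	gPRX	involved_in	MINI:0000002	MINI:fixture	IDA		P			protein	taxon:32630	20240101	MINI
MINI	gEGR2	gEGR2	involved_in	MINI:0000003	MINI:fixture	IDA		P			protein	taxon:32630	20240101	MINI
MINI	gGPI	gGPI	involved_in	MINI:0000005	MINI:fixture	IDA		P			protein	taxon:32630	20240101	MINI
MINI	gPOLG	gPOLG	involved_in	MINI:0000004	MINI:fixture	IDA		P			protein	taxon:32630	20240101	MINI
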