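gene_id	subfamily	length_aa	tify_hexamer	evidence_id	identity_pct	evalue
PH01000008G2960	JAZ	427	TIFYDG	bphyem207g19	100	0
PH01000038G0470	JAZ	208	TIFYGG	bphyem107e01	100	e-116
PH01000038G0510	JAZ	173	TIFYGG	bphyem202h03	82	7.00E-77
PH01000052G0540	JAZ	272	TIFYGG	JG297588.1
PH01000114G0660	ZML	303	TLSFQG
PH01000115G0020	JAZ	205	TIFYGG	bphyem118f19	100	e-115
PH01000115G0040	JAZ	183	TIFYGG	bphyem202h03	100	7.00E-99
PH01000158G0210	JAZ	235	TIFYGG
PH01000213G1380	JAZ	164	TIFYDG	bphyem116j13	81	2.00E-70
				JG297216.1		1.00E-92
PH01000213G1410	JAZ	178	TIIYGG	bphylf050a14	81	2.00E-73
PH01000310G0500	JAZ	245	TIFYGG	bphyem118e13	100	e-135
PH01000360G1030	JAZ	242	TIFYGG	bphyem205j14	100	e-136
PH01000361G0580	JAZ	209	TIFYDG
PH01000549G0400	TIFY	504	IIFYDG
PH01000597G0660	JAZ	208	TIFYGG	bphyem115l15	93	e-103
PH01000750G0690	ZML	258	TLVYQG	GH205920.1		1.00E-83
PH01000836G0660	ZML	470	TLSFQG
PH01000878G0620	ZML	1718	TLSFQG
PH01001078G0280	JAZ	163	TIFYGG
PH01001078G0420	JAZ	190	TIFYDG	bphyem116j13	99	e-104
				GH205920.1		2.00E-81
PH01001584G0350	ZML	344	TLLFQG
PH01001852G0020	JAZ	183	TIFYGG	bphyem122g05	100	e-100
PH01002950G0020	JAZ	411	TIFYAG	JG296527.1		e-125
PH01144128G0010	JAZ	193	TIFYDG	bphylf025d08	100	e-103
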