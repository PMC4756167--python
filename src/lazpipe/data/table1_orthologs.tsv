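soy_id	at_id	cluster	at_name
Glyma02g02630	AT3G01470		Homeobox 1, ATHB-1
Glyma17g35951	AT4G36930		SPATULA, SPT
Glyma18g51581	AT1G67260		TCP1
Glyma06g45554	AT3G23250		Myb domain protein 15
Glyma02g08241	AT3G54220		SCARECROW, SCR, SGR1, SHOOT GRAVITROPISM 1
Glyma03g34960	AT5G03680		PETAL LOSS, PTL
Glyma03g31530	AT4G14550	TF C1	Indole-3-acetic acid inducible 14, SOLITARY ROOT
Glyma19g34380	AT4G14550		Indole-3-acetic acid inducible 14, SOLITARY ROOT
Glyma02g16071	AT3G04730	TF C1	Indoleacetic acid-induced protein 16
Glyma13g22620	AT2G26580		YAB5, YABBY5
Glyma17g12200	AT2G26580	TF C1	YAB5, YABBY5
Glyma08g28691	AT1G67260	TF C1	TCP1
Glyma18g16390	AT3G01470	TF C1	Homeobox 1, ATHB-1
Glyma03g34710	AT5G03790	TF C1	HOMEOBOX 51, LATE MERISTEM IDENTITY1, LMI1
Glyma05g04260	AT2G45190	TF C1	ABNORMAL FLORAL ORGANS, AFO, FIL, YAB1, YABBY1
Glyma17g14710	AT2G45190	TF C1	ABNORMAL FLORAL ORGANS, AFO, FIL, YAB1, YABBY1
Glyma02g16080	AT3G23050	TF C1	Indole-3-acetic acid 7
Glyma04g10125	AT1G23420	TF C1	INNER NO OUTER, INO
Glyma06g10110	AT1G23420	TF C1	INNER NO OUTER, INO
Glyma19g36100	AT2G37260	TF C1	TRANSPARENT TESTA GLABRA 2, TTG2, WRKY44
Glyma08g39951	AT2G43060	TF C1	ILI1 binding bHLH 1
Glyma07g03840	AT3G15540	TF C1	Indole-3-acetic acid inducible 19
Glyma10g03720	AT3G23050		Indole-3-acetic acid 7
Glyma10g27881	AT3G62100		Indole-3-acetic acid inducible 30
Glyma08g40705	AT3G01470		Homeobox 1, ATHB-1
Glyma05g03020	AT1G66350		RGA-like 1
Glyma18g45220	AT3G54220		SCARECROW, SCR, SGR1, SHOOT GRAVITROPISM 1
Glyma19g05921	AT1G67260		TCP1
Glyma03g33376	AT2G37260		TRANSPARENT TESTA GLABRA 2, TTG2, WRKY44
Glyma10g07730	AT5G03680		PETAL LOSS, PTL
Glyma09g33241	AT5G10510		AINTEGUMENTA-like 6
Glyma03g19030	AT2G37630		ASYMMETRIC LEAVES 1, MYB91, PHANTASTICA-LIKE 1
Glyma02g40650	AT5G37020		Auxin response factor 8
Glyma15g01960	AT1G79840		GL2, GLABRA 2
Glyma13g37111	AT1G03790		SOMNUS (SOM)
Glyma03g06225	AT4G05100		Myb domain protein 74
Glyma04g03801	AT5G42630	TF C3	ABERRANT TESTA SHAPE, ATS, KAN4, KANADI 4
Glyma06g03901	AT5G42630		ABERRANT TESTA SHAPE, ATS, KAN4, KANADI 4
Glyma16g26291	AT3G26744	TF C4	ICE1, INDUCER OF CBF EXPRESSION 1, SCREAM
Glyma09g29940	AT1G17950		Myb domain protein 52
Glyma03g26520	AT2G44840		Ethylene-responsive element binding factor 13
Glyma14g10830	AT4G26150		CGA1, CYTOKININ-RESPONSIVE GATA1, GATA22, GNL
Glyma12g13710	AT4G28500		NAC PROTEIN 73, SECONDARY WALL-ASSOCIATED
Glyma17g06290	AT5G56860		GATA TRANSCRIPTION FACTOR 21, GNC
Glyma06g21495	AT5G61270		Phytochrome-interacting factor 7
Glyma08g02020	AT5G41410		BEL1, BELL 1
Glyma05g21726	AT4G32880		Homeobox gene 8, ATHB8
Glyma18g44030	AT2G38470		WRKY33
Glyma06g44250	AT4G28500	TF C5	NAC PROTEIN 73, SECONDARY WALL-ASSOCIATED
Glyma12g33460	AT4G28500	TF C5	NAC PROTEIN 73, SECONDARY WALL-ASSOCIATED
Glyma10g28820	AT1G23380		KNOTTED1-like homeobox gene 6
Glyma11g04910	AT4G37750		AINTEGUMENTA
Glyma18g04580	AT5G16600		Myb domain protein 43
Glyma10g27860	AT4G04450	TF C6	WRKY42
Glyma18g48730	AT2G44840		Ethylene-responsive element binding factor 13
Glyma05g38530	AT3G26744		ICE1, INDUCER OF CBF EXPRESSION 1, SCREAM
Glyma03g39041	AT1G23380		KNOTTED1-like homeobox gene 6
Glyma17g00650	AT2G02450		ANAC034, NAC 35, LONG VEGETATIVE PHASE 1
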