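generic	atc_code
omeprazole	A02BC01
esomeprazole	A02BC05
rabeprazole	A02BC04
sulfasalazine	A07EC01
diltiazem	C08DB01
bisoprolol	C07AB07
valsartan	C09CA03
imiquimod	D06BB10
azelaic acid	D10AX03
dupilumab	D11AH05
finasteride	G04CB01
lamivudine	J05AF05
nivolumab	L01FF01
pembrolizumab	L01FF02
atezolizumab	L01FF05
ipilimumab	L01FX04
mogamulizumab	L01FX09
vemurafenib	L01EC01
dabrafenib	L01EC02
encorafenib	L01EC03
trametinib	L01EE01
ribociclib	L01EF02
abemaciclib	L01EF03
busulfan	L01AB01
temozolomide	L01AX03
pemetrexed	L01BA04
tamoxifen	L02BA01
fulvestrant	L02BA03
anastrozole	L02BG03
letrozole	L02BG04
aldesleukin	L03AC01
infliximab	L04AB02
ustekinumab	L04AC05
secukinumab	L04AC10
ixekizumab	L04AC13
guselkumab	L04AC16
risankizumab	L04AC18
alemtuzumab	L04AG06
teprotumumab	S01XA26
alendronic acid	M05BA04
methylphenidate	N06BA04
chloroquine	P01BA01
omalizumab	R03DX05
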