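5	1253167	1295047	TERT
X	77504878	77786233	ATRX
2	15940550	15947007	MYCN
2	29192774	29921586	ALK
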