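5	1253287	1295162	TERT
X	76760356	77041702	ATRX
2	16080683	16087129	MYCN
2	29415640	30144432	ALK
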