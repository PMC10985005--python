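# Ancestral angiosperm mitochondrial gene clusters (name <TAB> comma-joined genes).
# Replaceable default table; the three best-attested clusters head the list,
# the remainder are conserved adjacencies reported across angiosperm mitogenomes.
nad3-rps12	nad3,rps12
rpl16-rps3-rps19-rpl2	rpl2,rps19,rps3,rpl16
trnP-sdh3	trnP,sdh3
cox3-sdh4	cox3,sdh4
nad4L-atp4	nad4L,atp4
rps10-cox1	rps10,cox1
rrn5-rrn18	rrn5,rrn18
rps13-nad1	rps13,nad1
nad1-matR	nad1,matR
ccmFn-rps1	ccmFn,rps1
rps14-cob	rps14,cob
trnY-trnE	trnY,trnE
trnfM-trnC	trnfM,trnC
trnD-trnW	trnD,trnW
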