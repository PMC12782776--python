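# synonym	canonical
# Editable mapping from annotation names (case-insensitive, punctuation stripped)
# to the controlled 38-label vocabulary (37 genes + CR).
nd1	ND1
nad1	ND1
nadh1	ND1
nadh dehydrogenase subunit 1	ND1
nd2	ND2
nad2	ND2
nadh2	ND2
nadh dehydrogenase subunit 2	ND2
nd3	ND3
nad3	ND3
nadh dehydrogenase subunit 3	ND3
nd4	ND4
nad4	ND4
nadh dehydrogenase subunit 4	ND4
nd4l	ND4L
nad4l	ND4L
nadh dehydrogenase subunit 4l	ND4L
nd5	ND5
nad5	ND5
nadh dehydrogenase subunit 5	ND5
nd6	ND6
nad6	ND6
nadh dehydrogenase subunit 6	ND6
cox1	COX1
co1	COX1
coi	COX1
cox i	COX1
cytochrome c oxidase subunit 1	COX1
cytochrome c oxidase subunit i	COX1
cox2	COX2
co2	COX2
coii	COX2
cytochrome c oxidase subunit 2	COX2
cytochrome c oxidase subunit ii	COX2
cox3	COX3
co3	COX3
coiii	COX3
cytochrome c oxidase subunit 3	COX3
cytochrome c oxidase subunit iii	COX3
atp6	ATP6
atpase6	ATP6
atp synthase f0 subunit 6	ATP6
atp8	ATP8
atpase8	ATP8
atp synthase f0 subunit 8	ATP8
cytb	CYTB
cob	CYTB
cyt b	CYTB
cytochrome b	CYTB
16s	rrnL
16s rrna	rrnL
16s ribosomal rna	rrnL
rrnl	rrnL
l-rrna	rrnL
large subunit ribosomal rna	rrnL
12s	rrnS
12s rrna	rrnS
12s ribosomal rna	rrnS
rrns	rrnS
s-rrna	rrnS
small subunit ribosomal rna	rrnS
trna-ile	trnI
trni	trnI
trna-gln	trnQ
trnq	trnQ
trna-met	trnM
trnm	trnM
trna-trp	trnW
trnw	trnW
trna-cys	trnC
trnc	trnC
trna-tyr	trnY
trny	trnY
trna-leu	trnL2
trnl	trnL2
trna-leu (uur)	trnL2
trnl2	trnL2
trna-leu (cun)	trnL1
trnl1	trnL1
trna-lys	trnK
trnk	trnK
trna-asp	trnD
trnd	trnD
trna-gly	trnG
trng	trnG
trna-ala	trnA
trna	trnA
trna-arg	trnR
trnr	trnR
trna-asn	trnN
trnn	trnN
trna-ser	trnS2
trns	trnS2
trna-ser (agn)	trnS1
trns1	trnS1
trna-ser (ucn)	trnS2
trns2	trnS2
trna-glu	trnE
trne	trnE
trna-phe	trnF
trnf	trnF
trna-his	trnH
trnh	trnH
trna-thr	trnT
trnt	trnT
trna-pro	trnP
trnp	trnP
trna-val	trnV
trnv	trnV
d-loop	CR
control region	CR
a+t rich region	CR
at-rich region	CR
cr	CR
putative control region	CR
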