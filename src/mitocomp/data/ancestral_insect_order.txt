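CR,trnI,-trnQ,trnM,ND2,trnW,-trnC,-trnY,COX1,trnL2,COX2,trnK,trnD,ATP8,ATP6,COX3,trnG,ND3,trnA,trnR,trnN,trnS1,trnE,-trnF,-ND5,-trnH,-ND4,-ND4L,trnT,-trnP,ND6,CYTB,trnS2,-ND1,-trnL1,-rrnL,-trnV,-rrnS
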