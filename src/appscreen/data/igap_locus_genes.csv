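chromosome,locus,gene
7,ZCWPW1,OR2AE1
7,ZCWPW1,GPC2
7,ZCWPW1,PVRIG
7,ZCWPW1,PILRA
7,ZCWPW1,AGFG2
8,PTK2B,TRIM35
8,PTK2B,EPHX2
14,FERMT2,FERMT2
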