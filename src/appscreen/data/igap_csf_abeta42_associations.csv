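chromosome,locus,gene,yfp_log2fc,yfp_log2fc_sd,mcherry_log2fc,mcherry_log2fc_sd,snp,beta,p_value
7,ZCWPW1,OR2AE1,-0.58,0.05,-1.18,0.07,rs35649099,-0.01422,0.2026
7,ZCWPW1,GPC2,-0.68,0.09,-1.45,0.32,rs12705074,-0.01702,0.0384
7,ZCWPW1,PVRIG,1.29,0.04,1.83,0.02,rs150436753,0.01965,0.1215
7,ZCWPW1,PILRA,1.17,0.10,1.43,0.16,rs28714213,0.01737,0.0171
7,ZCWPW1,AGFG2,-0.34,0.05,-1.21,0.16,rs78951820,-0.03433,0.0247
8,PTK2B,TRIM35,1.84,0.30,1.91,0.50,rs77389621,-0.02716,0.0584
8,PTK2B,EPHX2,-0.46,0.08,-1.42,0.30,rs7341557,0.02001,0.0160
14,FERMT2,FERMT2,1.19,0.34,1.67,0.28,rs62003531,-0.02745,0.0006
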