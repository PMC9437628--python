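gene_id,description,average_expression
7897877,TNFR,8.243984468
8177983,TNF-α,6.536676383
7957560,RAIDD,7.788116383
7941927,RIP,8.26486
8136869,CASP 2,8.382271277
8001938,TRADD,8.054042766
7942168,FADD,8.231118085
8047419,CASP 8 (pro CASP 8),6.960822128
8159476,TRAF2,7.739208936
8016194,NIK,7.416519362
7935707,IKK,8.132140851
8096635,NFkB,8.291935532
7943424,cIAP2,8.945781277
8150928,FAN,9.14069
7938100,acid_SMase,8.81918234
8121418,neutral_SMase,8.046917021
8034762,PKC,11.0
,SM*,8.0
,CAPK*,8.0
8114158,CAPP,10.96888511
7945666,Cathepsin D,11.5453383
8074261,BID,8.937911064
8103922,CASP3,7.36558
7912646,CASP9,8.748945106
8033151,CDase,6.900429787
8030078,SPHK,8.642491915
7903393,S1PR1,8.332580213
8133860,Gi,9.610689149
7945436,RasGDP,9.31107383
7947681,GAP,10.40175149
8084016,PI3K,9.115858298
8164328,PIP2,7.307359
7925531,AKT,11.38724894
8046408,PDK1,8.90167
8085164,RAF,9.895470426
7984319,MEK,10.74989787
8074791,ERK,12.18609574
,Mitochondria,8.0
8166402,SMS,9.51
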