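locus,repeat_structure,identified_allele
PentaE,AAGA (AAAGA)15,15.4
PentaE,(AAAGA)7 AAAA (AAAGA)7,14.4
PentaE,AAAGA AA (AAAGA)9,10.2
PentaE,AAGA (AAAGA)18,18.4
PentaD,AAAAA AAAG (AAAGA)9,10.4
D22S1045,(ATT)4 AT (ATT)4 ACT (ATT)2,11.2
SE33,CT (CTTT)3 C (CTTT)3 C (CTTT)11 (CTTT)3 CT (CTTT)2,13.3
SE33,CT (CTTT)3 C (CTTT)9T (CTTT)13 CT (CTTT)3 CT (CTTT)2,22.1
SE33,CT (CTTT) C (CTTT)3 C (CTTT)15 (CTTT)2 CT (CTTT)2,17.3
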