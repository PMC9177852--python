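patient_id,gene,aa_change,vaf_pct,co_mutation_phase
pt1,STAT5B,V712E,85.99,unknown
pt2,STAT5B,N642H,21.12,unknown
pt3,STAT3,K658R,26.79,monoallelic
pt3,STAT3,I659_M660insL,26.35,monoallelic
pt4,STAT3,D661Y,41.07,unknown
pt7,STAT5B,N642H,17.55,unknown
pt7,STAT5B,Q706L,14.34,unknown
pt8,STAT5B,N642H,10.74,monoallelic
pt8,STAT5B,L643M,10.41,monoallelic
pt9,STAT5B,Y665F,13.03,unknown
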