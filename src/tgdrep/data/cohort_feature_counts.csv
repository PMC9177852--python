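feature,symptomatic_pos,symptomatic_n,indolent_pos,indolent_n,hstcl_pos,hstcl_n,published_p
CD5,9,17,18,19,0,3,0.006
CD8,11,17,14,19,1,3,n.s.
HLA-DR,1,17,1,19,0,3,n.s.
CD16,16,17,17,19,3,3,n.s.
CD56,4,17,15,19,3,3,0.002
CD57,16,17,17,19,0,3,n.s.
CD158,7,16,7,19,3,3,n.s.
CD158a,0,16,3,19,3,3,n.s.
CD158b,6,16,5,19,3,3,n.s.
CD158e,2,16,2,19,2,3,n.s.
NKG2,6,16,14,19,3,3,0.031
NKG2A,3,16,14,19,0,3,0.002
NKG2C,3,16,0,19,3,3,n.s.
Vd1+/Vg9-,11,17,0,19,2,3,<0.0001
Vd2+/Vg9+,2,17,19,19,0,3,<0.0001
Vd1-/Vd2-,4,17,0,19,1,3,n.s.
CD28,0,11,0,14,,,n.s.
CD45RA,10,11,13,14,,,n.s.
CD45RO,6,11,14,14,,,0.009
CD62L,0,11,6,14,,,0.020
STAT_mutated,7,17,3,19,3,3,n.s.
STAT3_mutated,7,17,0,19,0,3,0.002
STAT5B_mutated,0,17,3,19,3,3,n.s.
neutropenia,16,17,0,19,1,3,<0.0001
anemia,9,17,0,19,2,3,<0.001
thrombocytopenia,2,17,0,19,3,3,n.s.
autoimmune_disease,8,17,2,19,0,3,0.025
splenomegaly,4,17,0,19,3,3,n.s.
secondary_neoplasia,5,17,3,19,0,3,n.s.
in_therapy,7,17,0,19,3,3,0.002
deceased,1,17,0,19,2,3,n.s.
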