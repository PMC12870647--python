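participant_id,ADOS_SocAff,ADOS_RRB,ADIR_A,ADIR_B,ADIR_C,ADIR_D,SRS_Aware,SRS_Cog,SRS_Comm,SRS_Mot,SRS_Mann,SCQ_Total
P00000,4,1,11,3,8,0,2,5,10,2,9,33
P00001,18,8,4,3,1,0,10,25,46,28,24,14
P00002,13,3,0,7,0,0,6,13,21,3,13,12
P00003,15,7,26,12,8,1,0,2,0,2,2,36
P00004,16,1,10,13,3,1,1,6,10,21,2,21
P00005,9,1,25,6,10,4,1,13,21,14,3,1
P00006,1,1,7,0,3,1,16,25,14,26,23,30
P00007,11,4,10,12,2,1,8,19,15,17,19,23
P00008,14,5,29,16,8,4,5,10,33,3,7,33
P00009,4,1,29,16,8,5,4,0,2,2,3,19
P00010,0,0,0,3,0,0,16,11,20,17,11,29
P00011,10,7,6,3,0,0,9,12,17,9,10,6
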