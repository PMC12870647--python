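participant_id,prs,total_brain_volume,mean_cortical_thickness
P00000,0.07800847499569472,1177182.6531630913,2.419792796926394
P00001,-0.7298864484582448,1260036.414614414,2.447546742627668
P00002,0.20979426601119774,1104864.9128156677,2.3991129611076794
P00003,0.7839376355411797,1050382.1459876625,2.5961955570761437
P00004,0.033515766598734675,1277801.8449756717,2.794896169188164
P00005,-1.0706436370933061,1165584.37338288,2.7915339648529036
P00006,0.17335843597060707,1072585.9071913238,2.515564320799775
P00007,1.7974728029624791,1309168.826681345,2.5115465238337844
P00008,-0.8377751178885502,998855.8297766286,2.5317358611937477
P00009,-0.5950240346010102,1079057.9347224387,2.3386365985774793
P00010,-0.8361083931195727,1454518.747839063,2.4282401832866274
P00011,-0.4539040697193342,1174815.8151018175,2.5051745051701455
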