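rsid	pleiotropy	functional	proxies
rs6265	Body mass index;Body weight;Smoking	0	NA
rs17685	NA	0	rs8565:0.845:25:A>A
rs1260326	Cholesterol;Triglycerides;Kidney diseases;C-reactive protein;Glucose tolerance test;Platelet count;Blood proteins	0	NA
rs1481012	Gout;Response to statin therapy	0	NA
rs2470893	NA	1	rs2472297:0.694:10:T>T
rs2472297	NA	1	NA
rs4410790	NA	1	NA
rs6968554	NA	0	NA
rs7800944	Triglycerides	0	rs14415:0.816:100:C>T
rs9902453	NA	0	NA
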