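	rs6265	rs17685	rs1260326	rs1481012	rs2470893	rs2472297	rs4410790	rs6968554	rs7800944	rs9902453	rs8565	rs14415
rs6265	1	0	0	0	0	0	0	0	0	0	0	0
rs17685	0	1	0	0	0	0	0	0	0	0	0.919239	0
rs1260326	0	0	1	0	0	0	0	0	0	0	0	0
rs1481012	0	0	0	1	0	0	0	0	0	0	0	0
rs2470893	0	0	0	0	1	0.833067	0	0	0	0	0	0
rs2472297	0	0	0	0	0.833067	1	0	0	0	0	0	0
rs4410790	0	0	0	0	0	0	1	0.92	0	0	0	0
rs6968554	0	0	0	0	0	0	0.92	1	0	0	0	0
rs7800944	0	0	0	0	0	0	0	0	1	0	0	0.903327
rs9902453	0	0	0	0	0	0	0	0	0	1	0	0
rs8565	0	0.919239	0	0	0	0	0	0	0	0	1	0
rs14415	0	0	0	0	0	0	0	0	0.903327	0	0	1
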