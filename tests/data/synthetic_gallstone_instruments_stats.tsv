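variant	effect_allele	other_allele	eaf	beta	se	p	n
rs11887534	G	C	0.3228274382235006	-0.3456897788102732	0.03259933729148804	2.8490227317794124e-26	27000
rs4245791	T	C	0.43759965987781024	0.16313259709169897	0.03353094161003327	1.1437802808810337e-06	27000
rs2547231	C	A	0.10326217998879095	-0.15600887606226505	0.04865943737663713	0.0013452940794141828	27000
rs1260326	T	C	0.34713901419610094	-0.40176377475330904	0.04675705007549129	8.503663110455877e-18	27000
rs6471717	A	G	0.8614032131708916	0.32614291427641756	0.028358990765568307	1.3113518677549001e-30	27000
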