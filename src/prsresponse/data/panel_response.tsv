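snp_id	chr	pos	effect_allele	other_allele	weight	p
rs6688363	1	160100000	T	C	1.0	1.6e-07
rs10170310	2	138800000	G	A	1.0	1.0e-07
rs2133450	3	7000000	C	A	1.0	4.3e-08
rs1875705	4	93900000	A	G	1.0	1.1e-08
rs10023464	4	23000000	T	C	1.0	9e-66
rs7668556	4	170000000	A	T	1.0	4e-13
rs17382202	5	58500000	T	C	1.0	4.2e-08
rs12767583	10	94760000	T	C	1.0	1e-16
rs7395555	11	60000000	C	G	1.0	2.0e-07
rs711355	15	30000000	T	C	1.0	2.3e-07
rs2980976	18	62340000	A	G	1.0	3.0e-07
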