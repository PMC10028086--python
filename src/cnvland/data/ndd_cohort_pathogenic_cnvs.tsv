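patient_id	sex	type	chrom	start	end	band
1	male	DEL	chr4	35031	4878160	4p16.3p16.2
19	male	DEL	chr15	22838642	28314382	15q11.2q13.1
20	female	DEL	chr20	8117650	8593664	20p12.3
35	female	DEL	chr15	22777709	28736935	15q11.2q13.1
40	female	DEL	chr17	16858825	20387706	17p11.2
53	female	DEL	chr1	168503684	191056769	1q24.2q31.2
59	male	DEL	chr17	36201251	37889808	17q12
86	male	DEL	chr18	45680	2276243	18p11.32
86	male	DEL	chr18	58298202	80227529	18q21.31q23
87	female	DEL	chr8	103458677	103560657	8q22.3
107	female	DEL	chr7	73294506	74715504	7q11.23
144	female	DEL	chr2	233505099	242065217	2q37.1q37.3
159	male	DEL	chr2	154077277	158596423	2q24.1
178	male	DEL	chr15	22600363	28760485	15q11.2q13.1
182	female	DEL	chr2	165992388	166079596	2q24.3
184	male	DEL	chr17	34815552	36249430	17q12
5	female	DUP	chr3	2299060	3322758	3p26.3p26.2
77	female	DUP	chr9	48828	39297860	9p24.3p12
14	male	DUP	chr11	114071597	125513912	11q23.2q24.2
15	female	DUP	chr14	90576836	106816816	14q32.11q32.33
2	male	DUP	chr15	23443797	28289373	15q11.2q13.1
101	female	DUP	chr15	23370969	28371148	15q11.2q13.1
79	male	DUP	chr17	151597	11392231	17p13.3p12
134	female	DUP	chr21	12987574	46679698	21q11.1q22.3
136	female	DUP	chr21	12987574	46679698	21q11.1q22.3
152	female	DUP	chr21	12987574	46679698	21q11.1q22.3
6	female	DUP	chr22	22749561	24600663	22q11.22q11.23
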