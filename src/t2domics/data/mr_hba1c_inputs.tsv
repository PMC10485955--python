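gene	snp	cpg	bx	bxse	by	byse	outcome_source
HK1	rs7909192	cg08992189	-100.2	16.1	0.08	0.0022	stanford_portal
HK1	rs75743765	cg08992189	-73.5	9.8	0.0456	0.0036	stanford_portal
HK1	rs11596193	cg08992189	-86.6	11.3	0.0277	0.004	gwas_catalogue
PFKFB2	rs1060286	cg22699725	65.04	10.10	-0.013	0.002	stanford_portal
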