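#source_gene	source_symbol	target_gene	operon	da_score	organism
b3404	EnvZ	SYNW0807	SYNW0807-0808	1	E_coli
b3405	OmpR	SYNW0808	SYNW0807-0808	0.99	E_coli
sll0689	NhaS3	SYNW0157		0.99	PCC6803
sll0493	KtrA	SYNW2169	SYNW2165-2170	0.56	PCC6803
slr1509	KtrB	SYNW2168	SYNW2165-2170	0.99	PCC6803
slr1508	KtrE	SYNW0663	SYNW0663-0667	0.99	PCC6803
b2741	Sigma38	SYNW1621		1	E_coli
sll0306	RpoD	SYNW0102	SYNW0101-0102	1	PCC6803
b0312	BetB	SYNW1956		0.99	E_coli
b0314	BetT	SYNW0229	SYNW0229-0233	0.99	E_coli
b4111	ProP	SYNW2494	SYNW2494-2495		E_coli
b2677	ProV	SYNW1915	SYNW1915-1917	0.56	E_coli
b2678	ProW	SYNW1916	SYNW1915-1917	0.99	E_coli
b2679	ProX	SYNW1917	SYNW1915-1917	0.99	E_coli
AB094497	GsmT	SYNW1914			A_halo
AB094498	SdmT	SYNW1913			A_halo
sll1566	GgpS	SYNW1281	SYNW1279-1286	0.99	PCC6803
slr0746	GgpP	SYNW0860			PCC6803
slr0747	GgtA	SYNW1285	SYNW1279-1286	0.99	PCC6803
slr0530	GgtC	SYNW1283	SYNW1279-1286	0.99	PCC6803
slr0531	GgtD	SYNW1284	SYNW1279-1286	0.99	PCC6803
ABX75857	GpgS	SYNW2436			P_mari
ABX75858	GpgP	SYNW2434			P_mari
slr0662	SpeA	SYNW2359		0.99	PCC6803
sll0045	Sps	SYNW2520		0.69	PCC6803
b0855	PotG	SYNW1544		0.99	E_coli
YP_225044	MtrA	SYNW2246			C_glut
YP_225045	MtrB	SYNW0551			C_glut
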