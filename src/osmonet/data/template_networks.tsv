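#organism	gene_id	symbol	role
A_halo	AB094497	GsmT	Betaine synthetase with glycine as the substrate
A_halo	AB094498	SdmT	Betaine synthetase with glycine as the substrate
A_halo	BAB69459	apNhaP	Na+/H+ antiporter
C_glut	cg1016	BetP	Betaine transporter
C_glut	cg0864	MtrB	Two-component system that senses osmotic stress
C_glut	cg0862	MtrA	Two-component system that senses osmotic stress
E_coli	b0019	NhaA	Na+ antiporter
E_coli	b1186	NhaB	Na+ antiporter
E_coli	b0020	NhaR	Na+/H+ antiporter regulator
E_coli	b3290	TrkA	Predominant K+ channel
E_coli	b1291	TrkE	Predominant K+ channel
E_coli	b1363	TrkG	Predominant K+ channel
E_coli	b3893	TrkH	Predominant K+ channel
E_coli	b3747	Kup	K+ channel playing a major role in neutral or slightly alkaline environments
E_coli	b0698	KdpA	High-affinity K+ channel playing a major role under osmotic stress
E_coli	b0697	KdpB	High-affinity K+ channel playing a major role under osmotic stress
E_coli	b0696	KdpC	High-affinity K+ channel playing a major role under osmotic stress
E_coli	b4513	KdpF	High-affinity K+ channel playing a major role under osmotic stress
E_coli	b0694	KdpE	Two-component system activating Kdp expression under osmotic stress
E_coli	b0695	KdpD	Two-component system activating Kdp expression under osmotic stress
E_coli	b0311	BetA	Betaine synthetase with proline as the substrate
E_coli	b0312	BetB	Betaine synthetase with proline as the substrate
E_coli	b0314	BetT	Proline transporter
E_coli	b1896	OtsA	Trehalose synthetase with UDPG as the substrate
E_coli	b1897	OtsB	Trehalose synthetase with UDPG as the substrate
E_coli	b2677	ProV	Betaine/proline transporter
E_coli	b2678	ProW	Betaine/proline transporter
E_coli	b2679	ProX	Betaine/proline transporter
E_coli	b2938	SpeA	Arginine synthetase
E_coli	b3404	EnvZ	Two-component system regulating OmpC and OmpF under osmotic stress
E_coli	b3405	OmpR	Two-component system regulating OmpC and OmpF under osmotic stress
E_coli	b0929	OmpF	Porin-encoding gene
E_coli	b2215	OmpC	Porin-encoding gene
E_coli	b4111	ProP	Betaine/proline transporter
E_coli	b2741	Sigma38	RNA polymerase, Sigma 38 (Sigma S) factor
E_coli	b1126	PotA	Putrescine/spermidine transporter
E_coli	b1125	PotB	Putrescine/spermidine transporter
E_coli	b1124	PotC	Putrescine/spermidine transporter
E_coli	b1123	PotD	Putrescine/spermidine transporter
E_coli	b0854	PotF	Putrescine transporter
E_coli	b0855	PotG	Putrescine transporter
E_coli	b0856	PotH	Putrescine transporter
E_coli	b0857	PotI	Putrescine transporter
P_mari	ABX75857	GpgS	Glucosylglycerate synthetase
P_mari	ABX75858	GpgP	Glucosylglycerate synthetase
PCC6803	sll0689	NhaS3	Na+/H+ antiporter
PCC6803	sll0493	KtrA	Predominant K+ transporter playing a major role in K+ uptake under osmotic stress
PCC6803	slr1509	KtrB	Predominant K+ transporter playing a major role in K+ uptake under osmotic stress
PCC6803	slr1508	KtrE	Predominant K+ transporter playing a major role in K+ uptake under osmotic stress
PCC6803	slr1728	KdpA	High-affinity K+ channel playing a minor role in K+ uptake under osmotic stress
PCC6803	slr1729	KdpB	High-affinity K+ channel playing a minor role in K+ uptake under osmotic stress
PCC6803	slr1730	KdpC	High-affinity K+ channel playing a minor role in K+ uptake under osmotic stress
PCC6803	slr1731	KdpD	Two-component system activating Kdp expression under osmotic stress
PCC6803	sll0045	SpsA	Sucrose synthetase
PCC6803	slr1312	SpeA	Arginine synthetase
PCC6803	slr0662	SpeA	Arginine synthetase
PCC6803	slr0747	GgtA	Glucosylglycerol/trehalose/sucrose transporter
PCC6803	slr0529	GgtB	Glucosylglycerol/trehalose/sucrose transporter
PCC6803	slr0530	GgtC	Glucosylglycerol/trehalose/sucrose transporter
PCC6803	slr0531	GgtD	Glucosylglycerol/trehalose/sucrose transporter
PCC6803	sll1546	GgpS	Glucosylglycerol synthetase
PCC6803	slr0746	GgpP	Glucosylglycerol synthetase
PCC6803	sll0306	RpoD	RNA polymerase, Sigma 70 (sigma D) factor
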