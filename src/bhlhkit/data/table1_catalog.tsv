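gene_name	group	family	protein_id	human_homologue	bi_support	ml_support	contig	chromosome
CASH1	A	ASCa	NP_989743.1	Hash1	83	71	NW_001471698.1	unknown
CASH2	A	ASCa	NP_990280.1	Hash2	93	n/m*	NW_001471698.1	unknown
CASH3a	A	ASCb	XP_001232099.1;XP_420985.2	Hash3a	100	89	NW_001471698.1	unknown
CASH3c	A	ASCb	XP_425485.1	Hash3c	51	89	NW_001471513.1	unknown
MYF3	A	MyoD	NP_989545.1	MYF3	88	95	NW_001471698.1	unknown
MYF4	A	MyoD	NP_989515.1	MYF4	100	94	NW_001471608.1	unknown
MYF5	A	MyoD	NP_001025534.1	MYF5	75	96	NW_001471512.1	1
MYF6	A	MyoD	NP_001025917.1	MYF6	93	99	NW_001471512.1	1
TF12a	A	E12/E47	NP_990706.2	TF12	54	78	NW_001471425.1	unknown
TF12b	A	E12/E47	hmm39106	TF12	54	78	NW_001471425.1	unknown
E2A	A	E12/E47	hmm9164	E2A	96	98	NW_001471627.1	unknown
TCF3	A	E12/E47	NP_989817.2	TCF3	98	97	NW_001471627.1	unknown
TCF4	A	E12/E47	Q90683.1	TCF4	55	n/m*	NW_001488824.1	unknown
CATH4a	A	Ngn	NP_990127.1	HATH4a	99	94	NW_001471685.1	unknown
CATH4c	A	Ngn	NP_990214.1	HATH4c	100	90	NW_001471449.1	unknown
NDF1	A	NeuroD	NP_990251.1	NDF1	55	n/m*	NW_001471729.1	unknown
CATH2	A	NeuroD	XP_418852.1	HATH2	97	89	NW_001471633.1	unknown
CATH3	A	NeuroD	NP_990407.1	HATH3	99	94	NW_001471747.1	unknown
CATH1a	A	Atonal	hmm54472	HATH1	100	87	NW_001471683.1	unknown
CATH1b	A	Atonal	XR_026796.1	HATH1	100	87	NW_001471683.1	unknown
CATH5	A	Atonal	NP_989999.1	HATH5	99	91	NW_001471715.1	unknown
Mist1	A	Mist	XP_425228.1	Mist1	100	98	NW_001471454.1	unknown
Beta3a	A	Beta3	NP_989835.1	Beta3a	57	62	NW_001471567.1	unknown
Beta3b	A	Beta3	NP_989834.1	Beta3b	95	76	NW_001471646.1	unknown
Oligo2	A	Oligo	NP_001026697.1	Oligo2	67	62	NW_001471669.1	3
Oligo3	A	Oligo	XP_001232806.1	Oligo3	84	76	NW_001471669.1	3
CATH6	A	Net	XP_001234980.1	HATH6	96	98	NW_001471687.1	unknown
Mesp1	A	Mesp	hmm11657	Mesp1;Mesp2	n/m	n/m	NW_001471429.1	unknown
Mesp2	A	Mesp	NP_989897.1	Mesp1;Mesp2	n/m	n/m	NW_001471429.1	unknown
pMesp1	A	Mesp	hmm17962	pMesp1;pMesp2	n/m	n/m	NW_001471429.1	unknown
pMesp2	A	Mesp	XP_001231219.1	pMesp1;pMesp2	n/m	n/m	NW_001471429.1	unknown
pMespo1	A	Mesp	NP_990015.1	pMesp1;pMesp2	n/m	n/m	NW_001471673.1	unknown
Twist1	A	Twist	NP_990070.1	Twist1	96	82	NW_001471633.1	unknown
Dermo-1a	A	Twist	NP_990010.1	Twist2	98	92	NW_001471728.1	unknown
Dermo-1b	A	Twist	NP_001096684.1	Twist2	100	98	NW_001471747.1	unknown
Dermo-1c	A	Twist	XP_424492.1	Twist2	100	98	NW_001471747.1	unknown
Paraxis	A	Paraxis	NP_990277.1	Paraxis	79	74	NW_001471567.1	unknown
Scleraxis1	A	Paraxis	NP_989584.1	Scleraxis	95	92	NW_001471733.1	unknown
Scleraxis2	A	Paraxis	XP_001234790.1	Scleraxis	91	97	NW_001471733.1	unknown
MyoRa1	A	MyoRa	XP_418293.2	MyoRa1	80	79	NW_001471650.1	2
MyoRa2	A	MyoRa	XP_419734.1	MyoRa2	100	n/m*	NW_001471669.1	unknown
MyoRb2	A	MyoRb	XP_427081.2	MyoRb2	85	n/m*	NW_001471649.1	2
Hand1	A	Hand	NP_990296.1	Hand1	99	91	NW_001471449.1	unknown
Hand2	A	Hand	NP_990297.1	Hand2	100	98	NW_001471685.1	unknown
PTFa	A	PTFa	XP_425989.1	PTFa	100	98	NW_001471633.1	unknown
PTFb	A	PTFb	XP_001234487.1	PTFb	99	95	NW_001471728.1	unknown
TAL1	A	SCL	NP_990683.1	TAL1	60	62	NW_001471740.1	unknown
TAL2	A	SCL	XP_424886.1	TAL2	99	82	NW_001488876.1	unknown
NSCL1	A	NSCL	NP_989452.1	NSCL1	100	99	NW_001471598.1	unknown
NSCL2	A	NSCL	NP_990128.1	NSCL2	72	85	NW_001471526.1	unknown
SRC1	B	SRC	NP_001012900.1	SRC1	91	98	NW_001471673.1	unknown
SRC2	B	SRC	XP_001231617.1	SRC2	100	98	NW_001471649.1	unknown
SRC3	B	SRC	XP_417385.2	SRC3	99	86	NW_001471567	unknown
v-MYC	B	Myc	NP_001026262.1	v-MYC	100	89	NW_001471673.1	unknown
c-MYC	B	Myc	NP_001026123.1	c-MYC	100	56	NW_001471654.1	unknown
L-MYC	B	Myc	XP_425790.1	L-MYC1;L-MYC2	98	98	NW_001471589.1	unknown
Mad1a	B	Mad	NP_001034399.1	Mad1 (Mxi1)	98	96	NW_001471581.1	unknown
Mad1c	B	Mad	NP_001012929.1	Mad1 (Mxi1)	98	74	NW_001471720.1	unknown
Mad4	B	Mad	NP_001006460.1	Mad4	100	85	NW_001471687.1	unknown
Mnt	B	Mnt	XP_425414.2	Mnt	98	68	NW_001471508.1	unknown
MAX	B	Max	P52162.1	MAX	100	91	NW_001471508.1	unknown
USF1	B	USF	NP_001007486.1	USF1	92	82	NW_001474499.1	unknown
MITF	B	MITF	NP_990360.1	MITF	100	64	NW_001471443.1	unknown
TFEB	B	MITF	NP_001026093.1	TFEB	100	96	NW_001471610.1	unknown
TFEC	B	MITF	NP_001006229.1	TFEC	100	71	NW_001471512.1	unknown
SREBP1	B	SREBP	NP_989457.1	SREBP1	100	96	NW_001471454.1	unknown
SREBP2	B	SREBP	XP_416222.2	SREBP2	100	99	NW_001471513.1	unknown
Mlx1	B	MLX	NP_001104311.1	Mlx	96	n/m*	NW_001471508.1	unknown
Mlx2	B	MLX	hmm20496	Mlx	96	n/m*	NW_001471508.1	unknown
MondoA	B	MLX	hmm54830	MondoA	100	91	NW_001471459.1	unknown
TF4	B	TF4	NP_001026101.1	TF4	100	83	NW_001471622.1	unknown
Clock	C	Clock	NP_989505.2	Clock	98	87	NW_001471686.1	unknown
NPAS2a	C	Clock	NP_001025713.1	NPAS2	100	97	NW_001471545.1	unknown
NPAS2b	C	Clock	XP_420353.2	NPAS2	100	99	NW_001471681.1	unknown
ARNT1	C	ARNT	NP_989531.1	ARNT1	100	100	NW_001471606.1	unknown
ARNT2	C	ARNT	XP_413854.2	ARNT2	100	100	NW_001471428.1	unknown
Bmal1	C	Bmal	NP_001001463.1	Bmal1	71	85	NW_001471698.1	unknown
Bmal2	C	Bmal	NP_989464.1	Bmal2	100	n/m*	NW_001471513.1	unknown
AHR1a	C	AHR	hmm34307	AHR1	68	94	NW_001471728.1	unknown
AHR1b	C	AHR	hmm34113	AHR1	68	94	NW_001471728.1	unknown
AHR2	C	AHR	hmm46108	AHR2	70	90	NW_001471639.1	unknown
Sim1	C	Sim	XP_419817.2	Sim1	74	n/m*	NW_001471671.1	unknown
Sim2	C	Sim	XP_416724.2	Sim2	93	88	NW_001471534.1	unknown
NPAS3	C	Trh	XP_421232.2	NPAS3	73	n/m*	NW_001471710.1	unknown
Hif1α	C	HIF	NP_989628.1	Hif1α	100	92	NW_001471710.1	unknown
EPAS1	C	HIF	NP_990138.1	EPAS1	100	91	NW_001471679.1	unknown
Id1	D	Emc	NP_989921.1	Id1	69	n/m*	NW_001471567.1	unknown
Id2	D	Emc	NP_990333.1	Id2	98	89	NW_001471673.1	unknown
Id3	D	Emc	NP_989920.1	Id3	100	96	none	unknown
Id4	D	Emc	NP_989613.1	Id4	91	86	NW_001471637.1	unknown
Herp1	E	Hey	XP_425926.2	Herp1	97	89	NW_001471651.1	unknown
Herp2	E	Hey	XP_419754.2	Herp2	66	73	NW_001471671.1	unknown
Dec1	E	H/E(spl)	hmm32419	Dec1	82	80	NW_001471443.1	unknown
Dec3a	E	H/E(spl)	XP_422641.2		n/m	n/m	NW_001471743.1	unknown
Dec3b	E	H/E(spl)	XP_416543.2		n/m	n/m	NW_001471526.1	unknown
Hes5a	E	H/E(spl)	NP_001012713.1	Hes5	75	78	NW_001471571.1	21
Hes5b	E	H/E(spl)	XP_417552.2	Hes5	n/m	97	NW_001471571.1	21
Hes5c	E	H/E(spl)	XP_417553.2	Hes5	n/m	97	NW_001471571.1	21
EBF1	F	Coe	NP_990083.1	EBF1	52	n/m*	NW_001471449.1	unknown
EBF2	F	Coe	XP_417675.2	EBF2	94	90	NW_001471575.1	unknown
EBF3	F	Coe	XP_421824.2	EBF3	67	n/m*	NW_001471723.1	unknown
Orphan2	orphan	Orphan	XP_422318.1		n/m	n/m	NW_001471740.1	unknown
Orphan3	orphan	Orphan	XP_001234727.1	Orphan3	100	93	NW_001471567.1	unknown
Orphan4	orphan	Orphan	XP_001235101.1		n/m	n/m	NW_001471508.1	unknown
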