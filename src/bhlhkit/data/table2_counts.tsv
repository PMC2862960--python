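family	group	Drosophila	Lancelet	Giant owl limpet	Chicken	Zebrafish	Rat	Mouse
ASCa	A	4	3	6	2	2	2	2
ASCb	A	0	1	1	2	3	3	3
MyoD	A	1	4	1	4	4	4	4
E12/E47	A	1	1	4	5	5	4	4
Ngn	A	1	1	3	2	2	3	3
NeuroD	A	0	1	1	3	5	4	4
Atonal	A	3	1	2	3	4	2	2
Mist	A	1	1	1	1	1	1	1
Beta3	A	1	1	2	2	3	2	2
Oligo	A	0	2	3	2	4	3	3
Net	A	1	1	2	1	1	1	1
Delilah	A	1	1	0	0	0	0	0
Mesp	A	1	1	0	5	5	3	3
Twist	A	1	1	2	4	3	2	2
Paraxis	A	1	2	1	3	4	2	2
MyoRa	A	1	4	1	2	2	2	2
MyoRb	A	0	1	1	1	2	2	2
Hand	A	1	1	1	2	1	2	2
PTFa	A	1	1	1	1	1	1	1
PTFb	A	2	3	1	1	2	1	1
SCL	A	1	1	5	2	3	3	3
NSCL	A	1	1	1	2	1	2	2
SRC	B	1	1	0	3	3	3	3
Figα	B	0	1	0	0	1	1	1
Myc	B	1	1	1	3	6	4	4
Mad	B	0	1	1	3	4	4	4
Mnt	B	1	1	1	1	2	1	1
Max	B	1	1	1	1	1	1	1
USF	B	1	1	2	1	2	2	2
MITF	B	1	1	1	3	5	4	4
SREBP	B	1	1	1	2	2	2	2
AP4	B	1	1	1	0	1	1	1
MLX	B	1	1	7	3	1	2	2
TF4	B	1	0	1	1	1	1	1
Clock	C	3	1	2	3	3	2	2
ARNT	C	1	1	0	2	2	2	2
Bmal	C	1	1	0	2	2	2	2
AHR	C	2	1	1	3	4	2	2
Sim	C	1	1	1	2	2	2	2
Trh	C	1	1	0	1	2	1	1
HIF	C	1	1	1	2	6	4	4
Emc	D	1	1	2	4	5	4	4
Hey	E	1	1	1	2	4	4	4
H/E(spl)	E	11	11	12	6	15	8	8
Coe	F	1	1	1	3	5	4	4
Orphan	?	0	6	4	3	2	4	4
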