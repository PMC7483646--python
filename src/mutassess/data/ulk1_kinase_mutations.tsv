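mutation	studies	revel	cooccurring_ulk2	dea	slim_ptm
G12D	GBM	0.308	NONE	Down
F14L	BLCA	0.205	NONE	No DE
A28V	GBM	0.377	NONE	Down
S56Y	UCEC*;COAD*	0.393	D73A;NONE	Down;No DE
L78Q	STAD*	0.539	NONE	Down(ULK2)
F81L	BLCA	0.215	R408S	No DE
N86T	UCEC*	0.049	NONE	Down
N96D	UCEC*	0.376	NONE	Down
A101T	UCEC*	0.373	T102A	Down
D102N	LGG	0.364	NONE	Down
D113E	HNSC	0.318	NONE	Up(ULK1)
A125T	COAD*	0.741	NONE	No DE
I135V	BLCA	0.14	NONE	No DE
R137H	STAD*	0.796	NONE	Down(ULK2)
R137C	COAD*	0.843	NONE	No DE	Introduce S-nitrosylation
D138N	LUSC;PAAD	0.769	NONE;NONE	Down;Down
R152L	LUAD*	0.226	NONE	Down(ULK2)
A154S	LIHC	0.06	NONE	Down(ULK2)
G167A	LUSC	0.91	NONE	Down
A169T	KIRP	0.751	NONE	No DE
Y171H	SKCM	0.121	R951K	Down(ULK1)
M177V	STAD*	0.632	NONE	Down(ULK2)
G183V	LUSC	0.766	NONE	Down
S184F	HNSC	0.797	NONE	Up(ULK1)
S195P	UCEC*	0.531	NONE	Down	Predicted phosphorylation by DNAPK or ATM kinases
V211I	UCEC*	0.04	NONE	Down
L215P	BRCA	0.716	NONE	No DE
E246D	COAD*	0.187	R254I	No DE
P250S	COAD*	0.082	NONE	No DE	Introduce phosphorylation by PKC kinase
R252L	LUSC	0.31	NONE	Down
R252W	STAD*	0.31	NONE	Down(ULK2)
R261C	STAD*	0.391	V868M	Down(ULK2)
R261H	PAAD	0.345	NONE	Down
D268H	OV	0.255	NONE
F273V	UCEC*	0.37	R303C
D279N	UCEC*	0.152	NONE		IAP-binding motif (279-283, ELM)
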