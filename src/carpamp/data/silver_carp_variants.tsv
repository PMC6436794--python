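#segment	cytb	1141
#segment	coi	1551
label	cytb:117	cytb:141	cytb:144	cytb:172	cytb:183	cytb:199	cytb:210	cytb:216	cytb:219	cytb:228	cytb:258	cytb:309	cytb:315	cytb:318	cytb:348	cytb:355	cytb:372	cytb:420	cytb:501	cytb:555	cytb:564	cytb:567	cytb:585	cytb:598	cytb:618	cytb:639	cytb:669	cytb:724	cytb:744	cytb:745	cytb:780	cytb:798	cytb:807	cytb:831	cytb:837	cytb:840	cytb:858	cytb:864	cytb:901	cytb:945	cytb:990	cytb:1002	cytb:1005	cytb:1035	cytb:1041	cytb:1050	cytb:1066	coi:147	coi:249	coi:264	coi:354	coi:390	coi:402	coi:492	coi:520	coi:561	coi:579	coi:595
A	A	T	A	G	C	G	T	C	A	A	A	T	A	C	A	T	G	T	C	A	C	C	G	C	C	T	C	T	T	C	C	G	A	T	C	T	C	G	C	A	A	T	G	T	C	C	G	T	G	A	T	A	C	C	C	T	A	T
B	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
C	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
D	.	.	.	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	.	.	T	.	.	.	.	.	.	C	.	.	.	.	.	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	G	.	.	.	.	.	.	.	.
E	G	.	.	C	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	T	.	.	.	.	.	.	C	.	.	.	.	.	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
F	.	.	.	.	T	.	.	.	.	.	.	.	G	.	.	C	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	T	.	.	.	.	.	T	.	.	.	.	.	.	.	A	G	.	.	.	T	.	.	.	.
G	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	C	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	A	.	.	T	.	.	.	.	.	T	.	.	.	.	.	.	.	A	G	.	.	.	T	.	.	.	.
H	.	C	G	.	.	.	C	T	.	G	G	C	.	T	G	C	A	C	T	G	T	.	A	T	T	C	T	C	C	A	T	A	G	C	T	C	T	A	.	G	.	C	A	C	T	T	A	C	A	G	C	C	T	.	T	C	G	C
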