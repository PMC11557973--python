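peptide	guest	membrane	deltaG
pep1	CB	POPC/POPG	4.853
pep1	CB	POPC	5.089
pep1	DPB	POPC/POPG	9.098
pep1	DPB	POPC	4.331
pep1	hCB	POPC/POPG	10.184
pep1	hCB	POPC	5.349
pep1	KB	POPC/POPG	2.757
pep1	KB	POPC	5.198
pep1	W	POPC/POPG	-7.369
pep1	W	POPC	-7.566
pep1	WB	POPC/POPG	10.225
pep1	WB	POPC	3.193
pep2	CB	POPC/POPG	9.158
pep2	CB	POPC	15.043
pep2	DPB	POPC/POPG	11.062
pep2	DPB	POPC	12.186
pep2	hCB	POPC/POPG	8.379
pep2	hCB	POPC	7.862
pep2	KB	POPC/POPG	8.436
pep2	KB	POPC	11.180
pep2	W	POPC/POPG	-1.174
pep2	W	POPC	2.204
pep2	WB	POPC/POPG	12.553
pep2	WB	POPC	16.292
pep3	W	POPC/POPG	-14.011
pep3	W	POPC	-4.298
pep3	WB	POPC/POPG	3.654
pep3	WB	POPC	8.723
pep4	W	POPC/POPG	7.490
pep4	W	POPC	4.447
pep4	WB	POPC/POPG	10.936
pep4	WB	POPC	13.538
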