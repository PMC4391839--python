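name	family	mature	accession	origin	arm	lm	lp	mfe	au_percent	is_star
mac-miR156	miR156/157	GUUGACAGAAGAUAGAAGAGCAC	JK538379	EST	5p	22	112	-52.60	50.0	0
mac-miR156a-5p	miR156/157	UGACAGAAGAGAGUGAGCAC	ES434836	EST	5p	20	94	-52.2	45.74	0
mac-miR156a-3p	miR156/157	GCUCACUUCUCUUCCUGUCAGC	ES434836	EST	3p	22	94	-52.2	45.74	0
mac-miR156d	miR156/157	UUGACAGAAGAUAGAGAGCAC	JK538379	EST	5p	21	112	-52.60	50.0	0
mac-miR156g	miR156/157	UGACAGAAGAUAGAGAGCAC	HN242063	GSS	5p	20	140	-68.80	49.29	0
mac-miR156h-3p	miR156/157	GCUCACUUCUCUUCCUGUCAGC	ES434836	EST	3p	22	94	-52.20	45.74	0
mac-miR157b-5p	miR156/157	UUGACAGAAGAUAGAGAGCAC	HN242063	GSS	5p	21	140	-68.80	49.29	0
mac-miR157b*	miR156/157	GCUCUCUAUGCUUCUGUCAUCA	HN242063	GSS	3p	22	140	-68.80	49.29	1
mbg-miR159	miR159/319	UUUGGAUUGAAGGGAGCUCUA	FL661284	EST	3p	21	129	-36.50	52.71	0
mac-miR319c	miR159/319	UUGGACUGAAGGGAGCUCCC	HN244586	GSS	5p	20	108	-20.1	56.48	0
mac-miR319m	miR159/319	UUGGACUGAAGGGAGCUCCCU	HN244586	GSS	5p	21	108	-20.1	56.48	0
mac-miR160a	miR160	UGCCUGGCUCCCUGUAUGCCA	JK538087	EST	3p	21	93	-20.9	50.54	0
mac-miR160g-5p	miR160	UGCCUGGCUCCCUGUAUGCCA	HN248011	GSS	5p	21	114	-49.30	47.37	0
mac-miR160g*	miR160	GCGUGCAAGGAGCCAAGCAUG	HN248011	GSS	3p	21	114	-49.30	47.37	1
mac-miR162	miR162	UCGAUAAACCGCUGCGUCCA	HN247504	GSS	3p	20	144	-53.40	50.69	0
mac-miR162*	miR162	GGAUGCAGAGGUUUAUCGACC	HN247504	GSS	3p	21	144	-53.40	50.69	1
mac-miR162b	miR162	UCGAUAAACCGCUGCGUCCAG	HN247504	GSS	3p	21	144	-53.40	50.69	0
mac-miR164e	miR164	UGGAGAAGCAGGGCACGUGCA	HN246671	GSS	5p	21	176	-68.0	49.43	0
mac-miR166	miR166	UCGGACCAGGCUUCAUUCCCCC	FF558732	EST	3p	22	85	-43.1	43.53	0
mac-miR166b	miR166	GGAAUGUUGUCUGGCUCGGGG	FF558732	EST	5p	21	85	-43.1	43.53	0
mac-miR166c-5p	miR166	GGAAUGUUGUCUGGCUCGAGG	FF558732	EST	5p	21	85	-43.1	43.53	0
mac-miR166c-3p	miR166	UCGGACCAGGCUUCAUUCCCC	FF558732	EST	3p	21	85	-43.1	43.53	0
mac-miR167c	miR167	UGAAGCUGCCAGCAUGAUCUG	HN250108	GSS	3p	21	149	-31.70	56.38	0
mac-miR167d	miR167	UGAAGCUGCCAGCAUGAUCUGG	HN250108	GSS	3p	22	149	-31.70	56.38	0
mac-miR169h	miR169	UAGCCAAGGAUGACUUGCCUG	JK539556	EST	5p	21	103	-52.2	44.66	0
mac-miR172b	miR172	UGAAUCUUAAUGAUGCUACA	HN239201	GSS	3p	20	123	-42.80	56.91	0
mac-miR172c	miR172	UGAAUCUUAAUGAUGCUACAC	HN239201	GSS	3p	21	123	-42.80	56.91	0
mbg-miR397a	miR397	UCAUUGAGUGCAGCGUUGAUG	FL666615	EST	5p	21	125	-58.50	49.60	0
mbg-miR399a	miR399	GUGCAGUUCUCCUCUUGGCAA	FL666459	EST	5p	21	92	-48.6	45.65	0
mbg-miR399a*	miR399	UGCCAAAGGAGAAUUGCCCUG	FL666459	EST	3p	21	92	-48.6	45.65	1
mac-miR4995	miR4995	AGGCAGUGGCUUGGUUAAGGG	DN238208	EST	3p	21	77	-21.80	44.16	0
mac-miR5538	miR5538	ACUGAACUCAAUCACUUGCUGC	DX457639	GSS	3p	22	131	-19.1	58.78	0
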