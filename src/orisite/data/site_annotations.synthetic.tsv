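# SYNTHETIC catalytic-site composition table (hand-curated, not a published
# survey): classic catalytic-site residue combinations used to build the
# bundled default amino-acid co-occurrence profile. Columns:
# structure_id  chain  resnum  icode  site_id  aa
syn001	A	57	-	1	HIS
syn001	A	102	-	1	ASP
syn001	A	195	-	1	SER
syn002	A	32	-	1	ASP
syn002	A	64	-	1	HIS
syn002	A	221	-	1	SER
syn003	A	57	-	1	HIS
syn003	A	102	-	1	ASP
syn003	A	189	-	1	SER
syn004	A	25	-	1	CYS
syn004	A	159	-	1	HIS
syn004	A	175	-	1	ASN
syn005	A	121	-	1	HIS
syn005	A	163	-	1	CYS
syn006	A	263	-	1	HIS
syn006	A	341	-	1	HIS
syn006	A	343	-	1	GLU
syn007	A	94	-	1	HIS
syn007	A	96	-	1	HIS
syn007	A	119	-	1	HIS
syn008	A	35	-	1	GLU
syn008	A	52	-	1	ASP
syn009	A	199	-	1	ASP
syn009	A	255	-	1	GLU
syn009	A	329	-	1	ASP
syn010	A	78	-	1	GLU
syn010	A	172	-	1	GLU
syn011	A	12	-	1	HIS
syn011	A	41	-	1	LYS
syn011	A	119	-	1	HIS
syn012	A	345	-	1	LYS
syn012	A	211	-	1	GLU
syn012	A	396	-	1	LYS
syn013	A	229	-	1	LYS
syn013	A	363	-	1	TYR
syn014	A	215	-	1	CYS
syn014	A	221	-	1	ARG
syn014	A	181	-	1	ASP
syn015	A	72	-	1	LYS
syn015	A	166	-	1	ASP
syn015	A	184	-	1	ASP
syn016	A	70	-	1	SER
syn016	A	73	-	1	LYS
syn016	A	166	-	1	GLU
syn017	A	32	-	1	ASP
syn017	A	215	-	1	ASP
syn018	A	143	-	1	GLU
syn018	A	142	-	1	HIS
syn018	A	146	-	1	HIS
syn019	A	165	-	1	GLU
syn019	A	95	-	1	HIS
syn019	A	14	-	1	TYR
syn020	A	51	-	1	HIS
syn020	A	68	-	1	GLU
syn020	A	115	-	1	ASN
syn021	A	209	-	1	SER
syn021	A	175	-	1	ASP
syn021	A	238	-	1	HIS
syn022	A	166	-	1	ARG
syn022	A	52	-	1	ASP
syn022	A	323	-	1	GLU
syn023	A	8	-	1	ASP
syn023	A	10	-	1	ASP
syn023	A	94	-	1	THR
syn024	A	73	-	1	SER
syn024	A	74	-	1	LYS
syn025	A	107	-	1	ASP
syn025	A	275	-	1	HIS
syn025	A	246	-	1	ASP
syn026	A	1	-	1	THR
syn026	A	33	-	1	LYS
syn027	A	69	-	1	LYS
syn027	A	231	-	1	HIS
syn028	A	439	-	1	CYS
syn028	A	272	-	1	TYR
syn029	A	14	-	1	ARG
syn029	A	62	-	1	HIS
syn030	A	38	-	1	ARG
syn030	A	42	-	1	HIS
syn030	A	191	-	1	TRP
syn031	A	40	-	1	GLY
syn031	A	84	-	1	ASP
syn031	A	96	-	1	HIS
syn032	A	118	-	1	ASN
syn032	A	119	-	1	GLY
syn032	A	204	-	1	GLU
syn033	A	160	-	1	GLY
syn033	A	164	-	1	LYS
syn033	A	58	-	1	TYR
syn034	A	88	-	1	MET
syn034	A	112	-	1	GLU
syn035	A	110	-	1	GLN
syn035	A	61	-	1	HIS
syn035	A	12	-	1	ARG
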