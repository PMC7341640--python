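gene_id	direction
VIM	up
RHOA	down
CDH2	down
CDH1	up
FN1	up
SNAI1	up
SNAI2	up
TWIST1	down
ZEB1	up
ZEB2	up
JUP	up
CLDN4	up
CLDN7	up
KRT18	up
KRT19	down
OCLN	down
DSP	down
MMP2	up
MMP9	down
SPARC	up
COL1A1	down
COL5A2	up
TGFB1	down
SERPINE1	down
VCAN	down
TNC	up
ITGB1	down
LOXL2	up
POSTN	down
SDC1	up
EPCAM	down
MUC1	up
CRB3	up
EMTG001	down
EMTG002	down
EMTG003	up
EMTG004	up
EMTG005	down
EMTG006	down
EMTG007	down
EMTG008	down
EMTG009	down
EMTG010	down
EMTG011	up
EMTG012	up
EMTG013	down
EMTG014	up
EMTG015	up
EMTG016	down
EMTG017	up
EMTG018	up
EMTG019	down
EMTG020	down
EMTG021	up
EMTG022	down
EMTG023	up
EMTG024	up
EMTG025	down
EMTG026	down
EMTG027	up
EMTG028	up
EMTG029	down
EMTG030	up
EMTG031	up
EMTG032	up
EMTG033	down
EMTG034	up
EMTG035	up
EMTG036	down
EMTG037	up
EMTG038	down
EMTG039	up
EMTG040	up
EMTG041	up
EMTG042	up
EMTG043	up
EMTG044	up
EMTG045	down
EMTG046	up
EMTG047	down
EMTG048	up
EMTG049	down
EMTG050	up
EMTG051	down
EMTG052	up
EMTG053	down
EMTG054	down
EMTG055	up
EMTG056	up
EMTG057	down
EMTG058	up
EMTG059	up
EMTG060	up
EMTG061	up
EMTG062	up
EMTG063	down
EMTG064	up
EMTG065	up
EMTG066	down
EMTG067	down
EMTG068	up
EMTG069	up
EMTG070	up
EMTG071	down
EMTG072	up
EMTG073	down
EMTG074	up
EMTG075	up
EMTG076	down
EMTG077	up
EMTG078	up
EMTG079	down
EMTG080	up
EMTG081	down
EMTG082	up
EMTG083	up
EMTG084	up
EMTG085	down
EMTG086	down
EMTG087	up
EMTG088	up
EMTG089	up
EMTG090	down
EMTG091	down
EMTG092	down
EMTG093	up
EMTG094	up
EMTG095	up
EMTG096	down
EMTG097	down
EMTG098	down
EMTG099	down
EMTG100	up
EMTG101	up
EMTG102	up
EMTG103	down
EMTG104	down
EMTG105	up
EMTG106	down
EMTG107	down
EMTG108	up
EMTG109	up
EMTG110	up
EMTG111	down
EMTG112	up
EMTG113	down
EMTG114	up
EMTG115	down
EMTG116	down
EMTG117	down
EMTG118	down
EMTG119	up
EMTG120	down
EMTG121	down
EMTG122	down
EMTG123	down
EMTG124	up
EMTG125	down
EMTG126	down
EMTG127	up
EMTG128	up
EMTG129	up
EMTG130	down
EMTG131	down
EMTG132	up
EMTG133	down
EMTG134	down
EMTG135	up
EMTG136	down
EMTG137	up
EMTG138	up
EMTG139	down
EMTG140	up
EMTG141	down
EMTG142	down
EMTG143	up
EMTG144	down
EMTG145	up
EMTG146	down
EMTG147	down
EMTG148	down
EMTG149	down
EMTG150	up
EMTG151	up
EMTG152	down
EMTG153	down
EMTG154	down
EMTG155	up
EMTG156	up
EMTG157	down
EMTG158	down
EMTG159	up
EMTG160	up
EMTG161	down
EMTG162	up
EMTG163	up
EMTG164	down
EMTG165	down
EMTG166	up
EMTG167	down
EMTG168	up
EMTG169	down
EMTG170	down
EMTG171	up
EMTG172	up
EMTG173	up
EMTG174	down
EMTG175	down
EMTG176	down
EMTG177	up
EMTG178	up
EMTG179	down
EMTG180	up
EMTG181	up
EMTG182	down
EMTG183	down
EMTG184	up
EMTG185	down
EMTG186	down
EMTG187	down
EMTG188	down
EMTG189	down
EMTG190	down
EMTG191	down
EMTG192	up
EMTG193	up
EMTG194	down
EMTG195	down
EMTG196	up
EMTG197	up
EMTG198	down
EMTG199	up
EMTG200	down
EMTG201	down
EMTG202	down
EMTG203	up
EMTG204	up
EMTG205	down
EMTG206	down
EMTG207	down
EMTG208	down
EMTG209	down
EMTG210	down
EMTG211	up
EMTG212	up
EMTG213	down
EMTG214	up
EMTG215	down
EMTG216	up
EMTG217	up
EMTG218	up
EMTG219	down
EMTG220	down
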