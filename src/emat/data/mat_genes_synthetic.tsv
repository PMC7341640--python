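gene_id	direction
VIM	up
RHOA	up
CDH2	up
ROCK1	up
ROCK2	up
ARHGDIB	down
MYL9	up
MYH9	up
LIMK1	up
PAK1	up
CFL1	down
EZR	down
MSN	up
RDX	up
CDC42	down
RAC1	down
ARPC2	up
PFN1	down
MYL12A	up
RND3	down
ARHGAP5	up
DIAPH1	down
WASF2	down
MATG001	up
MATG002	up
MATG003	down
MATG004	up
MATG005	down
MATG006	up
MATG007	down
MATG008	up
MATG009	down
MATG010	up
MATG011	up
MATG012	up
MATG013	up
MATG014	down
MATG015	down
MATG016	down
MATG017	up
MATG018	down
MATG019	down
MATG020	down
MATG021	down
MATG022	up
MATG023	down
MATG024	up
MATG025	up
MATG026	up
MATG027	down
MATG028	up
MATG029	up
MATG030	up
MATG031	down
MATG032	down
MATG033	up
MATG034	up
MATG035	down
MATG036	down
MATG037	down
MATG038	down
MATG039	down
MATG040	up
MATG041	up
MATG042	up
MATG043	down
MATG044	down
MATG045	up
MATG046	down
MATG047	down
MATG048	down
MATG049	up
MATG050	down
MATG051	down
MATG052	up
MATG053	up
MATG054	up
MATG055	up
MATG056	up
MATG057	down
MATG058	up
MATG059	up
MATG060	down
MATG061	up
MATG062	down
MATG063	up
MATG064	up
MATG065	down
MATG066	up
MATG067	down
MATG068	down
MATG069	down
MATG070	up
MATG071	down
MATG072	up
MATG073	down
MATG074	up
MATG075	down
MATG076	down
MATG077	down
MATG078	down
MATG079	up
MATG080	up
MATG081	up
MATG082	up
MATG083	up
MATG084	down
MATG085	up
MATG086	up
MATG087	up
MATG088	down
MATG089	down
MATG090	down
MATG091	up
MATG092	up
MATG093	up
MATG094	up
MATG095	down
MATG096	up
MATG097	up
MATG098	down
MATG099	up
MATG100	up
MATG101	up
MATG102	down
MATG103	up
MATG104	up
MATG105	down
MATG106	down
MATG107	up
MATG108	up
MATG109	up
MATG110	up
MATG111	up
MATG112	up
MATG113	down
MATG114	up
MATG115	down
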