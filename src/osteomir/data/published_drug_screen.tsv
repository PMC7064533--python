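name	drug_class	median_ic50_um	median_coefficient	chemical_replicates	limited_cell_lines	role
thapsigargin	SERCA inhibitor	0.003	0.273	1	0	candidate
daporinad	NAPRT inhibitor	0.004	0.323	1	0	candidate
paclitaxel	microtubule stabilizing agent	0.016	0.552	1	0	candidate
dinaciclib	CDK inhibitor	0.016	0.288	3	1	candidate
CGP-60474	CDK inhibitor	0.028	0.266	3	1	candidate
panobinostat	HDAC inhibitor	0.112	0.291	1	0	candidate
WH-4-023	Src inhibitor	0.156	0.268	2	1	candidate
methotrexate	DHFR inhibitor	0.160	NA	1	0	comparative
alvocidib	CDK inhibitor	0.221	0.283	3	1	candidate
irinotecan	topoisomerase inhibitor	0.444	0.265	4	0	candidate
doxorubicin	topoisomerase inhibitor	0.521	0.260	4	0	candidate
topotecan	topoisomerase inhibitor	0.698	0.273	4	0	candidate
trametinib	MEK inhibitor	0.897	0.270	2	0	candidate
AZ628	RAF inhibitor	0.966	0.256	1	1	candidate
TAE684	ALK inhibitor	1.143	0.266	1	0	candidate
dasatinib	Abl/Src inhibitor	2.846	0.304	2	0	candidate
pictilisib	PI3K inhibitor	3.359	0.452	1	0	candidate
etoposide	topoisomerase inhibitor	3.678	NA	4	0	comparative
tozasertib	aurora kinase inhibitor	4.504	0.377	1	0	candidate
PD-0325901	MEK inhibitor	5.199	0.292	2	0	candidate
nilotinib	Abl inhibitor	5.703	0.278	1	0	candidate
cisplatin	alkylating agent	8.414	NA	1	0	comparative
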