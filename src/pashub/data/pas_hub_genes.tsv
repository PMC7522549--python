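gene_id	log2fc_mrna	fdr_mrna	log2fc_protein	fdr_protein
COL17A1	6.693	0.001	1.288	0.003
MMP12	5.701	0.001	2.064	0.001
FSTL3	5.342	0.001	6.037	0.001
AGXT	4.899	0.001	5.501	0.001
INHA	4.123	0.001	1.094	0.035
LAMC2	3.975	0.001	5.614	0.001
HK2	3.525	0.001	5.534	0.001
LAMB3	3.423	0.005	6.519	0.001
APOBR	3.275	0.003	5.973	0.001
MORF4L2	2.403	0.001	5.581	0.001
GDPD3	2.055	0.001	1.739	0.006
HID1	-2.308	0.001	-4.205	0.012
CSF3R	-1.949	0.003	-1.287	0.001
WNT3A	-1.904	0.021	-4.3	0.007
RASIP1	-1.856	0.017	-1.034	0.030
PODXL	-1.819	0.049	-1.273	0.001
ADGRA2	-1.741	0.001	-2.249	0.001
RALGAPA2	-1.662	0.031	-1.303	0.002
ERVW-1	-1.206	0.033	-1.87	0.001
JCAD	-1.196	0.028	-6.379	0.001
SYMPK	-1.19	0.011	-5.956	0.001
TEAD3	-1.131	0.008	-1.326	0.001
INTS3	-1.116	0.023	-2.236	0.001
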