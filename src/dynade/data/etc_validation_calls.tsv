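gene	selected_qpcr	selected_affy	go_group	cluster
ATP5A1	1	0	A	
ATP5C1	1	1	N	3
ATPIF1	1	0	A	
ATP5F1	1	1	A,N	2
ATP5G1	0	0		
ATP5I	1	1	N	2
ATP5L	0	0	A	
ATP5O	1	0		
BTF3	1	1	A	2
CYCS	1	1	A	2
COX17	1	1		3
COX6B1	1	1		3
COX5B	1	1		3
COX7B	1	0		
COX7C	1	1		3
NARG1	1	1	A	7
NDUFA2	1	1	I	2
NDUFA3	1	1	I	2
NDUFA6	1	1	I	2
NDUFA7	1	1	I	2
NDUFA12	1	1	I	2
NDUFB2	1	1	I	2
NDUFB3	0	1	I	2
NDUFS1	1	1	A,I	2
NDUFS4	1	1	I	2
NDUFV2	1	0	I	
SDHA	1	0		
SDHB	1	1	A	2
SLC25A6	1	0	A	
UCP2	0	0	A	
UQCRB	1	1		3
UQCRC2	1	0	A	
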