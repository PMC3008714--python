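electron_transport_chain	mitochondrial oxidative phosphorylation gene set	ATP5A1	ATP5C1	ATP5F1	ATP5G1	ATP5I	ATP5L	ATP5O	ATPIF1	BTF3	COX17	COX5B	COX6B1	COX7B	COX7C	CYCS	NARG1	NDUFA12	NDUFA2	NDUFA3	NDUFA6	NDUFA7	NDUFB2	NDUFB3	NDUFS1	NDUFS4	NDUFV2	SDHA	SDHB	SLC25A6	UCP2	UQCRB	UQCRC2
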