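source	target	standardized_weight	p_value
FAS2.1	FAS1.1	0.894	***
FAS2.1	PAH1	0.695	***
FAS1.1	ACC1	0.668	***
PAH1	DGA2	0.827	***
PAH1	ACC1	0.339	***
ACC1	SCT1	1.148	***
DGA2	SCT1	0.306	***
FAS2.1	SCT1	-0.555	***
FAS2.1	ACL1	0.765	***
DGA2	SLC1	0.572	***
ACC1	tid_2139	0.443	***
SCT1	ACL2	-0.112	***
PAH1	tid_2139	-0.193	0.002
FAS1.1	PDB1	0.436	***
ACL1	oil productivity	0.487	***
ACC1	oil productivity	-0.36	0.007
FAS1.1	oil productivity	0.687	***
FAS2.1	oil productivity	-0.479	0.002
SLC1	oil productivity	-0.254	0.007
DGA2	oil productivity	0.488	***
FAS2.1	FAA1	1.117	***
PAH1	MDH1	0.619	***
PDB1	MDH1	0.615	***
ACC1	FAA1	0.786	***
oil productivity	MDH1	-0.107	0.005
FAS1.1	MDH1	-0.802	***
FAS1.1	FAA1	-0.98	***
DGA2	FAA1	-0.175	***
ACC1	MDH1	0.608	***
MDH1	FBP2	0.486	***
MDH1	GPD1	0.327	***
SLC1	GPD1	0.3	***
PDB1	GPD1	0.422	***
PDB1	FBP2	0.254	***
SLC1	FBP2	-0.182	***
ACL2	FBP2	0.3	***
FAA1	GPD1	-0.398	***
PAH1	GPD1	0.362	***
ACL1	ACL2	0.991	***
PDB1	tid_2139	0.504	***
ACL1	PDB1	0.429	***
PDB1	ACL2	0.081	***
tid_2139	SLC1	-0.342	***
tid_2139	ACL1	0.26	***
SLC1	PDB1	-0.225	***
ACL2	SLC1	0.545	***
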