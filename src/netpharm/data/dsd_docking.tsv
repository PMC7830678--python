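compound	EGFR	CUL3	APP	MCM2	CDK2	FN1
Senkyunolide A	-5.72	-5.87	-5.33	-6.33	-5.43	-6.31
Senkyunolide G	-5.91	-6.31	-5.7	-6.63	-5.92	-5.1
Senkyunolide I	-6.44	-5.94	-6.3	-6.41	-6.22	-5.36
Ferulic acid	-6.5	-5.61	-6.46	-7.44	-7.01	-5.94
Ferulaldehyde	-5.82	-5.03	-5.2	-6.52	-5.98	-5.38
O-Methoxycinnamal	-5.01	-5.09	-5.37	-6.01	-5.68	-5.02
Cinnamic acid	-5.34	-5.23	-5.82	-5.82	-5.23	-4.97
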