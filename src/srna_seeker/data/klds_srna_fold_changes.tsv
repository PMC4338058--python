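srna_id	acid	bile	git
IGR-113	1.63	3.86	0.29
IGR-130	1.26	1.25	0.94
IGR-136	0.98	1.84	0.59
IGR-2	0.70	1.05	1.25
IGR-217	2.15	3.26	0.33
IGR-33	0.90	1.44	0.26
IGR-36	1.11	1.24	0.86
IGR-392	4.12	1.55	0.65
IGR-466	0.96	1.99	0.47
IGR-64	1.92	1.76	0.50
IGR-93	2.50	1.19	0.63
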