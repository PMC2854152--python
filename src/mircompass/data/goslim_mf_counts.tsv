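category	non_up	up	down	non_down
DNA or RNA binding	1479	4	7	1476
hydrolase activity	2107	17	18	2106
kinase activity	1174	7	2	1179
nucleic acid binding	431	3	1	433
nucleotide binding	1000	2	2	1000
other binding	2127	19	17	2129
other enzyme activity	2225	16	13	2228
other molecular functions	699	2	4	697
protein binding	1775	5	12	1768
receptor binding or activity	181	1	1	181
structural molecule activity	385	1	1	385
transcription factor activity	1358	16	10	1364
transferase activity	1664	15	10	1669
transporter activity	1028	9	1	1036
unknown molecular functions	5635	15	30	5620
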