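description	pfam_id	n_contigs	gc_percent	per_kb_control	per_kb_nacl	per_kb_tmac
Protein kinase domain	Pkinase	938	42.5	21.3	51.6	48.6
PPR (pentatricopeptide) repeat	PPR	364	38.9	27.7	69.3	60.2
Cytochrome P450	p450	241	43.1	25.9	62.3	59.3
WD domain, G-beta repeat	WD40	136	43.1	20.1	45.1	41.4
NB-ARC domain	NB-ARC	116	39.6	33.3	84.2	70.8
Leucine Rich Repeat	LRR_1	108	42.4	23.5	66.9	63.8
Myb-like DNA-binding domain	Myb_DNA-binding	98	43.3	21.2	47.3	43.0
RNA recognition motif	RRM_1	98	44.4	17.2	38.7	34.4
UDP-glucoronosyl and UDP-glucosyl transferase	UDPGT	83	45.2	24.0	55.4	58.1
TIR domain	TIR	74	40.2	28.6	65.3	57.5
Transferase family	Transferase	73	44.2	23.2	54.6	57.3
Peroxidase	peroxidase	69	44.6	24.3	54.2	53.6
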