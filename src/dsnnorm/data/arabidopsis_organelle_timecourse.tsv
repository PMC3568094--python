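library	hours	chloroplast_reads	mitochondrion_reads
0 hrs-DSN	0	637508	89756
22 hrs+DSN	22	141235	61172
46 hrs+DSN	46	109516	46243
70 hrs+DSN	70	79305	34111
94 hrs+DSN	94	83457	29819
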