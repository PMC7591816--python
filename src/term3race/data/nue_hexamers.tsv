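sequence	class_tag	rice_rank	at_rank_a	at_rank_b	note
AAUAAA	canonical	1	1	1	canonical plant poly(A) signal
AAUAAG	aauaaa_like	18	60	301
AAUGAA	aauaaa_like	16	21	59
AAUCAA	aauaaa_like	72	33	139
AAUUAA	aauaaa_like	7	63	115
UAUAAA	aauaaa_like	0	10	21	not ranked in rice NUE survey
AAGAAA	aauaaa_like	15	18	43
GAAUAA	nue_enriched	2	32	149
AUGAAU	nue_enriched	17	39	103	top-ranking NUE hexamer recurrent in composite signals
AUAAAU	nue_enriched	90	5	12
GAAGAA	nue_enriched	113	205	354
UGAAAU	nue_enriched	43	53	75
AAAGGA	nue_enriched	76	0	0
GAAUGA	nue_enriched	73	222	0
AAAUUU	nue_enriched	20	16	18
ACAAGU	nue_enriched	100	594	0
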