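hexamer	rank	note
AATAAA	1	canonical
ATTAAA	2	variant
TATAAA	3	variant
AGTAAA	4	variant
AAGAAA	5	variant
AATATA	6	variant
AATACA	7	variant
CATAAA	8	variant
GATAAA	9	variant
AATGAA	10	variant
ACTAAA	11	variant
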