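# Default PAS hexamer variant table: the AATAAA consensus plus the
# single-substitution variants commonly recovered in large-scale poly(A)
# site surveys, in descending usage order (rank 1 = most used).
# Columns: hexamer <tab> usage_rank.  Replace with your own table to match
# a specific survey.
AATAAA	1
ATTAAA	2
TATAAA	3
AGTAAA	4
AAGAAA	5
AATATA	6
AATACA	7
CATAAA	8
GATAAA	9
AATGAA	10
ACTAAA	11
AATAGA	12
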