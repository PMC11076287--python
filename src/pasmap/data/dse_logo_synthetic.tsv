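# SYNTHETIC downstream-sequence-element (DSE) frequency logo.
# A U/G-rich profile constructed to have the qualitative shape of published
# DSE logos; it is a stand-in for demonstrations and tests only.  For real
# analyses supply the position-frequency matrix of a published DSE logo.
# Columns: A C G T (tab-separated), one row per motif position; rows sum to 1.
0.15	0.05	0.20	0.60
0.05	0.05	0.55	0.35
0.08	0.04	0.18	0.70
0.05	0.05	0.45	0.45
0.12	0.08	0.20	0.60
0.06	0.04	0.30	0.60
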