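# Per-position mismatch penalty weights for SpCas9 specificity scoring
# (experimentally derived 20-position matrix; position 0 = PAM-distal end).
# Columns: position<TAB>weight
0	0.000
1	0.000
2	0.014
3	0.000
4	0.000
5	0.395
6	0.317
7	0.000
8	0.389
9	0.079
10	0.445
11	0.508
12	0.613
13	0.851
14	0.732
15	0.828
16	0.615
17	0.804
18	0.685
19	0.583
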