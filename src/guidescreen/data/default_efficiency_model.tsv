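# Illustrative positional-linear efficiency model (NOT a trained fit).
# Swap in trained coefficients with the same format to use a real model.
# Window = flank5(10) + spacer(20) + flank3(10); position 0 = first context base.
# All weights non-negative: scores are bounded below by the intercept.
#intercept	0.10
10	G	0.020
10	A	0.010
12	C	0.015
15	G	0.025
18	A	0.020
20	C	0.030
22	G	0.040
24	T	0.005
25	G	0.060
25	C	0.040
25	A	0.020
26	G	0.055
26	C	0.035
27	G	0.050
27	A	0.025
28	G	0.045
28	C	0.030
29	G	0.065
29	C	0.045
29	A	0.015
31	G	0.020
33	C	0.015
36	A	0.010
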