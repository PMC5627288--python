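# Default TMT10 reporter-ion isotope-impurity fixture, version 1.
# Leakage in percent of each channel's own signal into neighbouring
# channels (by channel index). Representative magnitudes; real values
# are printed on the lot-specific reagent certificate.
channel	minus2	minus1	plus1	plus2
126	0.0	1.2	2.9	0.3
127N	0.1	1.4	2.7	0.2
127C	0.0	1.6	2.5	0.3
128N	0.1	1.8	2.4	0.2
128C	0.2	2.0	2.2	0.1
129N	0.1	2.1	2.0	0.2
129C	0.2	2.3	1.8	0.1
130N	0.1	2.5	1.6	0.2
130C	0.3	2.7	1.3	0.1
131	0.2	2.9	1.1	0.0
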