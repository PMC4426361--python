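# Nearest-neighbor duplex formation parameters (Breslauer et al. 1986).
# stack: 5'->3' dinucleotide on the top strand (complement implied).
# dH: kcal/mol (formation, negative); dS: cal/(mol*K) (formation, negative).
# The 6 non-listed stacks are reverse complements of listed ones.
# initiation: dH 0, dS -10.8 cal/(mol*K)  (helix initiation entropy).
stack	dH	dS
AA	-9.1	-24.0
AT	-8.6	-23.9
TA	-6.0	-16.9
CA	-5.8	-12.9
GT	-6.5	-17.3
CT	-7.8	-20.8
GA	-5.6	-13.5
CG	-11.9	-27.8
GC	-11.1	-26.7
GG	-11.0	-26.6
init	0.0	-10.8
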