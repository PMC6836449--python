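# SYNTHETIC stand-in score table generated deterministically by
# scripts/make_score_tables.py; not empirically fitted values.
# Guide bases use the DNA alphabet (T for rU).
pam_suffix	score
AA	0.0
AC	0.0
AG	0.26
AT	0.0
CA	0.01
CC	0.0
CG	0.11
CT	0.0
GA	0.07
GC	0.02
GG	1.0
GT	0.02
TA	0.0
TC	0.0
TG	0.04
TT	0.0
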