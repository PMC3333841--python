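dinuc1	dinuc2	dH	dS
AA	AA	-7.9	-22.2
TT	TT	-7.9	-22.2
AT	AT	-7.2	-20.4
TA	TA	-7.2	-21.3
CA	CA	-8.5	-22.7
TG	TG	-8.5	-22.7
GT	GT	-8.4	-22.4
AC	AC	-8.4	-22.4
CT	CT	-7.8	-21.0
AG	AG	-7.8	-21.0
GA	GA	-8.2	-22.2
TC	TC	-8.2	-22.2
CG	CG	-10.6	-27.2
GC	GC	-9.8	-24.4
GG	GG	-8.0	-19.9
CC	CC	-8.0	-19.9
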