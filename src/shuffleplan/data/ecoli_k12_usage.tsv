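codon	fraction
TTT	0.57
TTC	0.43
TTA	0.13
TTG	0.13
CTT	0.10
CTC	0.10
CTA	0.04
CTG	0.50
ATT	0.51
ATC	0.42
ATA	0.07
ATG	1.00
GTT	0.26
GTC	0.22
GTA	0.15
GTG	0.37
TCT	0.15
TCC	0.15
TCA	0.12
TCG	0.15
AGT	0.15
AGC	0.28
CCT	0.16
CCC	0.12
CCA	0.19
CCG	0.53
ACT	0.17
ACC	0.44
ACA	0.13
ACG	0.26
GCT	0.16
GCC	0.27
GCA	0.21
GCG	0.36
TAT	0.57
TAC	0.43
CAT	0.57
CAC	0.43
CAA	0.35
CAG	0.65
AAT	0.45
AAC	0.55
AAA	0.77
AAG	0.23
GAT	0.63
GAC	0.37
GAA	0.69
GAG	0.31
TGT	0.45
TGC	0.55
TGG	1.00
CGT	0.38
CGC	0.40
CGA	0.06
CGG	0.10
AGA	0.04
AGG	0.02
GGT	0.34
GGC	0.40
GGA	0.11
GGG	0.15
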