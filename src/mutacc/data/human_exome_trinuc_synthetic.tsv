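# SYNTHETIC stand-in for a human-exome trinucleotide frequency table.
# Generated from an i.i.d. GC=0.52 sequence with CpG dinucleotides thinned to
# ~25% of their i.i.d. rate (mutacc.simulate.exome_like_trinuc_freqs, seed=11,
# 400 kb). Replace with a table derived from a real exome for production use.
# Columns: pyrimidine-collapsed trinucleotide, relative frequency (sums to 1).
trinucleotide	frequency
ACA	0.03711018555
ACC	0.03442267211
ACG	0.00873004365
ACT	0.03667518338
CCA	0.0449402247
CCC	0.04335521678
CCG	0.01058255291
CCT	0.04494272471
GCA	0.03328766644
GCC	0.03150765754
GCG	0.008002540013
GCT	0.03332266661
TCA	0.03661268306
TCC	0.03453517268
TCG	0.0086600433
TCT	0.03704518523
ATA	0.02952264761
ATC	0.0281001405
ATG	0.03664268321
ATT	0.02927514638
CTA	0.03621268106
CTC	0.03488767444
CTG	0.04416272081
CTT	0.03672268361
GTA	0.02795263976
GTC	0.02604263021
GTG	0.03488517443
GTT	0.02805514028
TTA	0.02997014985
TTC	0.02782263911
TTG	0.0362601813
TTT	0.02975264876
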