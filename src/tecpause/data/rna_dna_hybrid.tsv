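# kind: RNA:DNA
# source: RNA/DNA hybrid nearest-neighbor set (Sugimoto et al. 1995, Table 3),
#         measured in 1 M NaCl, 10 mM Na2HPO4, 1 mM Na2EDTA, pH 7.0
# key: coding-strand dinucleotide, 5'->3', written in DNA letters (U -> T);
#      the coding strand is the RNA strand, the template strand is DNA
# units: dH kcal/mol, dS cal/(mol K); melting free energy at T is -(dH - T*dS/1000)
stack	dH_kcal_mol	dS_cal_mol_K
AA	-7.8	-21.9
AC	-5.9	-12.3
AG	-9.1	-23.5
AT	-8.3	-23.9
CA	-9.0	-26.1
CC	-9.3	-23.2
CG	-16.3	-47.1
CT	-7.0	-19.7
GA	-5.5	-13.5
GC	-8.0	-17.1
GG	-12.8	-31.9
GT	-7.8	-21.6
TA	-7.8	-23.2
TC	-8.6	-22.9
TG	-10.4	-28.4
TT	-11.5	-36.4
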