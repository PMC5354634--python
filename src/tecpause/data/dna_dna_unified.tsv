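# kind: DNA:DNA
# source: unified oligonucleotide nearest-neighbor set (SantaLucia 1998, Table 2)
# key: coding-strand dinucleotide, 5'->3'; duplex with its reverse complement
# units: dH kcal/mol, dS cal/(mol K); melting free energy at T is -(dH - T*dS/1000)
# note: entries satisfy reverse-complement symmetry E(xy) = E(rc(xy))
stack	dH_kcal_mol	dS_cal_mol_K
AA	-7.9	-22.2
AC	-8.4	-22.4
AG	-7.8	-21.0
AT	-7.2	-20.4
CA	-8.5	-22.7
CC	-8.0	-19.9
CG	-10.6	-27.2
CT	-7.8	-21.0
GA	-8.2	-22.2
GC	-9.8	-24.4
GG	-8.0	-19.9
GT	-8.4	-22.4
TA	-7.2	-21.3
TC	-8.2	-22.2
TG	-8.5	-22.7
TT	-7.9	-22.2
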