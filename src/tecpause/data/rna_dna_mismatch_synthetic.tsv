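# kind: RNA:DNA-mismatch (SYNTHETIC stand-in)
# source: synthetic reconstruction -- matched RNA/DNA hybrid stacks (Sugimoto 1995)
#         destabilized by an enthalpic per-stack penalty chosen per mismatch identity.
#         Covered mismatches (one per template base): rU.dT, rG.dG, rC.dC, rA.dA,
#         keyed by the coding-strand base at the error position (A, C, G, T resp.).
#         Per-stack ddG penalties (kcal/mol): rG.dG 0.5 < rU.dT 0.8 < rA.dA 1.2 < rC.dC 1.3,
#         matching the qualitative stability ordering of internal RNA/DNA mismatches.
#         These are NOT measured values; quantitative mismatch conclusions should be
#         re-derived with measured internal-mismatch parameters.
# key: stack = coding-strand dinucleotide 5'->3' (U -> T); mismatch_at marks which of
#      the two bases carries the transcriptional error (5p or 3p)
# units: dH kcal/mol, dS cal/(mol K)
stack	mismatch_at	dH_kcal_mol	dS_cal_mol_K
AA	5p	-7.0	-21.9
AA	3p	-7.0	-21.9
AC	5p	-5.1	-12.3
AC	3p	-5.4	-12.3
AG	5p	-8.3	-23.5
AG	3p	-7.8	-23.5
AT	5p	-7.5	-23.9
AT	3p	-7.1	-23.9
CA	5p	-8.5	-26.1
CA	3p	-8.2	-26.1
CC	5p	-8.8	-23.2
CC	3p	-8.8	-23.2
CG	5p	-15.8	-47.1
CG	3p	-15.0	-47.1
CT	5p	-6.5	-19.7
CT	3p	-5.8	-19.7
GA	5p	-4.2	-13.5
GA	3p	-4.7	-13.5
GC	5p	-6.7	-17.1
GC	3p	-7.5	-17.1
GG	5p	-11.5	-31.9
GG	3p	-11.5	-31.9
GT	5p	-6.5	-21.6
GT	3p	-6.6	-21.6
TA	5p	-6.6	-23.2
TA	3p	-7.0	-23.2
TC	5p	-7.4	-22.9
TC	3p	-8.1	-22.9
TG	5p	-9.2	-28.4
TG	3p	-9.1	-28.4
TT	5p	-10.3	-36.4
TT	3p	-10.3	-36.4
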