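# graphamp nearest-neighbour parameter file, table id "unified-v1"
# Unified DNA nearest-neighbour duplex parameters (1 M NaCl reference state).
# stack rows: 5'->3' dinucleotide on the top strand of a Watson-Crick duplex,
#   dH in kcal/mol, dS in cal/(mol K).
# init rows: duplex initiation terms per terminal base pair (init_GC, init_AT)
#   and the self-complementary symmetry correction (symmetry: dS only).
# loop rows: hairpin-loop initiation free energy dG at 37 C (kcal/mol) for
#   loop sizes 3-30 nt; sizes beyond 30 are extrapolated logarithmically as
#   dG(n) = dG(30) + 1.75 * R * T * ln(n/30).
# Salt handling (documented, applied in code, not in this file):
#   dS_corrected = dS + 0.368 * N_stacks * ln([Na+]_eq in mol/L)
#   [Na+]_eq (mM) = monovalent_mM + 120 * sqrt(divalent_mM)
type	key	dH_kcal_per_mol	dS_cal_per_mol_K
stack	AA	-7.9	-22.2
stack	AT	-7.2	-20.4
stack	AC	-8.4	-22.4
stack	AG	-7.8	-21.0
stack	TA	-7.2	-21.3
stack	TT	-7.9	-22.2
stack	TC	-8.2	-22.2
stack	TG	-8.5	-22.7
stack	CA	-8.5	-22.7
stack	CT	-7.8	-21.0
stack	CC	-8.0	-19.9
stack	CG	-10.6	-27.2
stack	GA	-8.2	-22.2
stack	GT	-8.4	-22.4
stack	GC	-9.8	-24.4
stack	GG	-8.0	-19.9
init	init_GC	0.1	-2.8
init	init_AT	2.3	4.1
init	symmetry	0.0	-1.4
loop	3	3.5	.
loop	4	3.5	.
loop	5	3.3	.
loop	6	4.0	.
loop	7	4.1	.
loop	8	4.3	.
loop	9	4.4	.
loop	10	4.4	.
loop	11	4.6	.
loop	12	4.7	.
loop	13	4.8	.
loop	14	5.0	.
loop	15	5.1	.
loop	16	5.2	.
loop	17	5.3	.
loop	18	5.4	.
loop	19	5.4	.
loop	20	5.5	.
loop	21	5.6	.
loop	22	5.6	.
loop	23	5.7	.
loop	24	5.7	.
loop	25	5.8	.
loop	26	5.8	.
loop	27	5.9	.
loop	28	5.9	.
loop	29	6.0	.
loop	30	6.0	.
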