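# Adduct-ion rows of the published metabolite summary table (one row per
# detected adduct ion; dual-polarity metabolites contribute two rows).
# printed_formula, printed_exact_mass and printed_ppm are retained verbatim
# as provenance; `formula` is the composition adopted by this package.
# For M19 the adopted composition is C27H36O19 (consistent with the
# narrative C7H6 loss, the printed exact mass, and the -1.938 ppm scale);
# the table's printed composition C31H36O16 is kept in printed_formula.
# Matrix codes: 1 plasma, 2 urine, 3 feces, 4 liver, 5 kidney, 6 brain.
feature_id	metabolite	rt_min	polarity	adduct	mz	formula	printed_formula	printed_exact_mass	printed_ppm	identification	sham_matrices	model_matrices
M0p	M0	10.12	+	[M+Na]+	777.22101	C34H42O19	C34H42O19	754.23148	-0.309	DISS	1,2,3,6	1,2,6
M0n	M0	10.11	-	[M-H]-	753.22528	C34H42O19	C34H42O19	754.23148	2.157	DISS	1,2,3,6	1,2,6
M1p	M1	5.78	+	[M+Na]+	571.16290	C23H32O15	C23H32O15	562.15284	-0.773	6'-Sinapoyl sucrose	2,3,6	2,6
M1n	M1	5.78	-	[M-H]-	547.16669	C23H32O15	C23H32O15	562.15284	1.724	6'-Sinapoyl sucrose	2,3,4,6	2,6
M2	M2	6.61	+	[M+H]+	227.09128	C11H14O5	C11H14O5	226.08357	-0.529	C-O bond rupture reduction product of DISS	2,3,4,5,6	2,3,4,5,6
M3	M3	7.96	+	[M+H]+	227.12766	C12H18O4	C12H18O4	226.11996	-0.553	Methylation product of M2	1,2,3,4,5,6	1,2,3,4,5,6
M4	M4	8.13	-	[M-H]-	339.10873	C16H20O8	C16H20O8	340.11527	3.792	DISS demethoxylation product	1,2,3,4,5	1,2,3,4,5,6
M5p	M5	8.14	+	[M+Na]+	735.17440	C31H36O19	C31H36O19	712.18453	0.1914	Demethylation product of DISS	2	2
M5n	M5	8.13	-	[M-H]-	711.17834	C31H36O19	C31H36O19	712.18453	2.299	Demethylation product of DISS	2	2
M6	M6	8.46	+	[M+H]+	227.09129	C11H14O5	C11H14O5	226.08357	-0.485	C-O bond rupture reduction product of DISS	3,6	2,3,4,5,6
M7	M7	8.61	+	[M+H]+	225.07570	C11H12O5	C11H12O5	224.06792	-0.222	Sinapinic acid	2	2,4,5
M8	M8	10.90	+	[M+H]+	243.08733	C11H14O6	C11H14O6	242.07849	1.921	Hydroxylation of sinapic acid	1,2,3,6	1,2,3,6
M9	M9	11.21	+	[M+H]+	341.12158	C16H20O8	C16H20O8	340.11527	-4.438	DISS demethoxylation product	1,4,5,6	1,2,3,4,5
M10p	M10	12.77	+	[M+Na]+	395.13052	C17H24O9	C17H24O9	372.14148	-1.856	DISS glycosidic bond rupture product	2,3	2,3
M10n	M10	12.75	-	[M-H]-	371.13492	C17H24O9	C17H24O9	372.14148	3.399	DISS glycosidic bond rupture product	2,3	2,3
M11	M11	13.39	+	[M+Na]+	395.13120	C17H24O9	C17H24O9	372.14148	-0.388	DISS C=O bond fracture product	1,2,4,5,6	1,2,4,5,6
M12	M12	13.90	+	[M+H]+	241.10716	C12H16O5	C12H16O5	240.09922	0.456	Methylated product after reduction of sinapinic acid	2	2
M13p	M13	13.56	+	[M+Na]+	251.08891	C11H16O5	C11H16O5	228.09923	-0.338	Sinapinic acid addition product	1,2,3,4,5,6	1,2,3,4,6
M13n	M13	13.52	-	[M-H]-	227.09253	C11H16O5	C11H16O5	228.09923	4.976	Sinapinic acid addition product	1,2,3,6	1,2,3,6
M14	M14	14.48	-	[M-H]-	371.13239	C17H24O9	C17H24O9	372.14148	-3.418	DISS glycosidic bond rupture product	2,3,6	2,6
M15	M15	14.64	-	[M-H]-	223.09724	C12H16O4	C12H16O4	224.10431	3.382	Reductive product of M12	1,2,3,6	1,2,3,6
M16p	M16	15.32	+	[M+H]+	727.28077	C34H46O17	C34H46O17	726.27295	-1.947	DISS reduction product	2	2
M16n	M16	15.30	-	[M-H]-	725.26600	C34H46O17	C34H46O17	726.27295	1.2745	DISS reduction product	2	2
M17p	M17	15.69	+	[M+H]+	729.29643	C34H48O17	C34H48O17	728.28860	-4.986	Reduction product of dehydroxy DISS	1,2,3,6	1,2,3,6
M17n	M17	15.70	-	[M-H]-	727.28078	C34H48O17	C34H48O17	728.28860	-0.135	Reduction product of dehydroxy DISS	1	
M18	M18	16.04	+	[M+H]+	227.12790	C12H18O4	C12H18O4	226.11996	0.5040	Position isomer of M3	1,4,6	1,4,5,6
M19	M19	23.05	-	[M-H]-	663.17542	C27H36O19	C31H36O16	664.18453	-1.938	Demethylation product of DISS	1,2,3	1,2,3,6
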