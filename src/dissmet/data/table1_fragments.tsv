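# MS2 fragment peaks transcribed from the published metabolite table.
# formula is the printed ion composition (blank where none was printed);
# rel_intensity is percent of the base peak. Several printed compositions
# are not element-wise sub-formulas of their precursor ions or disagree
# with their printed m/z; they are retained verbatim and flagged by
# dissmet.annotate.validate_printed_fragments, never corrected.
feature_id	mz	formula	rel_intensity
M0p	777.22113	C34H42O19Na	100
M0p	409.11023	C17H22O10Na	21.58
M0p	391.09967	C17H20O9Na	6.09
M0n	205.05049	C11H9O4	100
M0n	190.02710	C10H6O4	88.42
M0n	175.00372	C9H3O4	28.26
M0n	547.16614	C23H31O15	12.27
M0n	164.04791	C9H8O3	8.76
M0n	223.06189	C11H11O5	7.23
M1p	571.16266	C23H32O15Na	100
M1p	409.10941	C17H22O10Na	22.62
M1p	391.10001	C17H20O9Na	6.90
M1n	205.05058	C11H9O4	100
M1n	190.02713	C10H6O4	57.13
M1n	175.00354	C9H3O4	20.99
M1n	547.16681	C23H31O15	18.35
M1n	223.06117	C11H11O5	11.96
M2	181.04924	C9H9O4	100
M2	227.09102	C11H15O5	26.19
M2	209.08060	C11H13O4	21.94
M2	167.07001	C9H11O3	6.11
M3	85.06531	C5H9O	100
M3	149.09598	C10H13O	63.70
M3	191.10643	C12H15O2	61.59
M3	209.11690	C12H17O3	60.39
M3	227.12654		37.93
M4	339.05457	C11H15O12	100
M4	259.09747	C15H15O4	57.77
M4	229.08693	C14H13O3	55.89
M4	122.03733	C7H6O2	9.81
M4	134.03729	C8H6O2	7.20
M4	295.09653	C18H15O4	5.07
M5p	70.06594		100
M5p	245.11336	C13H18O3Na	41.27
M5p	227.10280	C13H16O2Na	36.82
M5p	277.11856	C15H15O2	32.87
M5p	249.12337	C16H18ONa	27.44
M5p	325.17694	C19H26O3Na	26.45
M5p	343.18710	C19H28O4Na	24.09
M5p	201.12357	C12H18ONa	21.03
M5n	321.04388	C11H13O11	100
M5n	241.08717	C15H13O3	25.58
M5n	322.04718	C18H10O6	13.30
M5n	294.13840	C23H18	10.90
M6	167.07014	C9H11O3	100
M6	177.05444	C10H9O3	5.15
M6	209.08076	C11H13O4	3.85
M7	207.06502	C11H11O4	100
M7	175.03889	C10H7O3	63.01
M7	192.04141	C10H8O4	21.64
M7	149.02347	C8H5O3	7.54
M7	164.04666	C9H8O3	5.36
M8	243.08736	C11H15O6	100
M8	172.08670		40.40
M8	216.07651		29.79
M8	198.06587		15.69
M8	197.08096	C10H13O4	0.46
M9	341.22040		100
M9	238.19051	C13H27O2Na	4.07
M9	205.08562	C11H9O4	2.72
M9	323.09164	C19H15O5	2.71
M9	191.07014	C11H11O3	2.70
M9	107.08558	C8H11	2.32
M9	163.07523	C10H11O2	2.16
M10p	395.28958	C25H40O2Na	100
M10p	377.27933	C25H38ONa	36.24
M10p	107.08579	C6H12Na	9.68
M10p	271.12012	C11H20O6Na	5.33
M10p	359.26834	C25H36Na	5.17
M10n	147.11789		100
M10n	371.17041	C18H27O8	67.35
M10n	209.11717	C12H17O3	4.69
M10n	179.05547		2.83
M10n	191.10738		2.68
M10n	149.04442	C5H9O5	2.16
M10n	293.94162		1.78
M10n	207.10025		1.73
M11	395.20325	C19H32O7Na	100
M11	203.05223	C6H12O6Na	23.02
M11	201.03685	C6H10O6Na	6.26
M11	217.15601	C13H22ONa	5.52
M11	215.14053	C13H20ONa	4.39
M11	121.10120	C9H13	1.80
M12	241.16249		100
M12	123.116687	C9H15	25.31
M12	147.11676	C11H15	13.58
M13p	98.98458		100
M13p	251.08862	C11H16O5Na	76.53
M13p	251.12540	C12H20O4Na	61.89
M13p	141.09071	C6H14O2Na	7.51
M13p	167.08630	C11H12Na	6.81
M13p	173.13144	C11H18Na	5.06
M13n	227.12891	C12H19O4	100
M13n	183.13898	C11H19O2	30.81
M13n	165.12851	C11H17O	27.80
M13n	209.11829	C12H17O3	25.19
M14	371.11700	C13H23O12	100
M14	291.16016	C17H23O4	66.46
M14	79.95737		30.93
M14	247.17033	C16H23O2	30.14
M14	371.24493		24.66
M14	122.03730		17.26
M14	123.04517		13.98
M14	135.04510		13.06
M15	223.11705	C9H19O6	100
M15	122.10566	C9H14	13.98
M15	179.12711	C8H19O	44.85
M16p	409.09137	C22H17O8	100
M16p	427.10205	C22H19O9	98.04
M16p	391.08096	C22H15O7	72.55
M16p	379.08099	C21H15O7	71.11
M16p	511.12332	C26H23O11	50.98
M16p	481.11246	C25H21O10	50.12
M16p	325.07050	C18H13O6	40.00
M16p	349.07037	C20H13O6	33.57
M16p	337.07034	C19H13O6	24.35
M16p	355.08121	C19H15O7	23.50
M16n	353.06680		100
M16n	443.09808	C22H19O10	76.65
M16n	473.10849	C23H21O11	34.99
M16n	725.19037	C32H37O19	33.48
M16n	545.12988	C26H25O13	18.62
M16n	413.08752	C21H17O9	15.06
M16n	407.07764	C22H15O8	11.06
M17p	127.03926	C6H7O3	100
M17p	189.08713	C12H13O2	53.89
M17p	156.07675	C8H12O3	41.81
M17p	155.08171	C12H11	19.55
M17p	213.09970	C7H17O7	16.21
M17p	159.07664	C11H11O	15.36
M17n	212.00232		100
M17n	217.01762	C4H9O10	43.23
M17n	80.96514		21.35
M17n	261.00748	C12H5O7	17.73
M17n	213.00554	C8H5O7	10.55
M17n	137.06081	C8H9O2	10.27
M18	227.06352	C12H12O3Na	100
M18	209.11656	C12H17O3	71.14
M19	112.98559		100
M19	323.22034	C19H31O4	32.70
M19	255.23296	C16H31O2	25.16
M19	391.20743	C29H27O	10.03
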