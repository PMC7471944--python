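# RNA dinucleotide property table, version 1.
# 16 dinucleotides x 15 properties covering 11 physico-chemical, conformational
# and thermodynamic quantities (hydrophilicity, enthalpy, entropy and free
# energy each appear twice, from two published determinations).
# Sources: conformational step parameters (twist, rise, shift, tilt, slide,
# roll) and stacking energies from published RNA duplex structural/energetic
# compilations as collected in the DiProDB dinucleotide property database;
# enthalpy_1/entropy_1/free_energy_1 from the Freier et al. (1986)
# nearest-neighbour set; enthalpy_2/entropy_2/free_energy_2 from the
# Xia et al. (1998) nearest-neighbour set; hydrophilicity_1 and
# hydrophilicity_2 from two published dinucleotide hydrophilicity scales.
# Which duplicate maps to _1 vs _2 is this package's documented convention.
# Units: twist/tilt/roll in degrees; rise/shift/slide in Angstrom; stacking
# energy, enthalpy and free energy in kcal/mol; entropy in cal/(mol K);
# hydrophilicity dimensionless.
dinucleotide	twist	rise	shift	tilt	slide	roll	stacking_energy	hydrophilicity_1	hydrophilicity_2	enthalpy_1	enthalpy_2	entropy_1	entropy_2	free_energy_1	free_energy_2
AA	31.0	3.18	-0.08	-0.8	-1.27	7.0	-13.7	0.023	0.04	-6.6	-6.82	-18.4	-19.0	-0.9	-0.93
AC	32.0	3.24	0.23	0.8	-1.43	4.8	-13.8	0.083	0.14	-10.2	-11.40	-26.2	-29.5	-2.1	-2.24
AG	30.0	3.30	-0.04	0.5	-1.50	8.5	-14.0	0.035	0.08	-7.6	-10.48	-19.2	-27.1	-1.7	-2.08
AU	33.0	3.24	-0.06	1.1	-1.36	7.1	-15.4	0.090	0.14	-5.7	-9.38	-15.5	-26.7	-0.9	-1.10
CA	31.0	3.09	0.11	1.0	-1.46	9.9	-14.4	0.118	0.21	-10.5	-10.44	-27.8	-26.9	-1.8	-2.11
CC	32.0	3.32	-0.01	0.3	-1.78	8.7	-11.1	0.349	0.49	-12.2	-13.39	-29.7	-32.7	-2.9	-3.26
CG	27.0	3.30	0.30	-0.1	-1.89	12.1	-15.6	0.193	0.35	-8.0	-10.64	-19.4	-26.7	-2.0	-2.36
CU	30.0	3.30	-0.04	0.5	-1.50	8.5	-14.0	0.378	0.52	-7.6	-10.48	-19.2	-27.1	-1.7	-2.08
GA	32.0	3.38	0.07	1.3	-1.70	9.4	-14.2	0.048	0.10	-13.3	-12.44	-35.5	-32.5	-2.3	-2.35
GC	35.0	3.22	0.07	0.0	-1.39	6.1	-16.9	0.146	0.26	-14.2	-14.88	-34.9	-36.9	-3.4	-3.42
GG	32.0	3.32	-0.01	0.3	-1.78	8.7	-11.1	0.065	0.17	-12.2	-13.39	-29.7	-32.7	-2.9	-3.26
GU	32.0	3.24	0.23	0.8	-1.43	4.8	-13.8	0.160	0.27	-10.2	-11.40	-26.2	-29.5	-2.1	-2.24
UA	32.0	3.26	-0.02	-0.2	-1.45	10.7	-13.2	0.112	0.21	-8.1	-7.69	-22.6	-20.5	-1.1	-1.33
UC	32.0	3.38	0.07	1.3	-1.70	9.4	-14.2	0.359	0.48	-13.3	-12.44	-35.5	-32.5	-2.3	-2.35
UG	31.0	3.09	0.11	1.0	-1.46	9.9	-14.4	0.224	0.34	-10.5	-10.44	-27.8	-26.9	-1.8	-2.11
UU	31.0	3.18	-0.08	-0.8	-1.27	7.0	-13.7	0.389	0.44	-6.6	-6.82	-18.4	-19.0	-0.9	-0.93
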