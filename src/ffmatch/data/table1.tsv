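# CB8-guest standard binding free energies, kcal/mol.
# dg_exp: experimental reference values; dg_<set>: computed estimates under
# four bonded parameter sets (GAFF, GAFF2 and the two force-matched refits
# FM-PM6 and FM-BLYP, all sharing one RESP charge set); sd_<set>: standard
# error of each estimate from block analysis.
# G5 appears as two protonation variants sharing one experimental value; the
# scored G5 estimate is the mean of the two rows.
guest	dg_exp	dg_GAFF	sd_GAFF	dg_GAFF2	sd_GAFF2	dg_FM-PM6	sd_FM-PM6	dg_FM-BLYP	sd_FM-BLYP
G1	-7.05	-5.9	0.4	-8.0	0.4	-7.4	0.4	-7.4	0.4
G2	-9.93	-8.2	0.5	-11.3	0.5	-9.1	0.5	-10.0	0.5
G3	-11.63	-14.9	0.4	-8.5	0.5	-8.6	0.5	-11.4	0.4
G4	-11.22	-9.9	0.5	-5.5	0.5	-6.6	0.4	-14.7	0.4
G5 prot	-12.32	-3.5	0.5	-8.3	0.5	-6.4	0.5	-9.2	0.5
G5 deprot	-12.32	-10.4	0.5	-10.9	0.5	-8.0	0.5	-16.0	0.5
G6	-14.07	-12.4	0.5	-14.1	0.5	-12.8	0.5	-11.0	0.4
G7	-7.92	-8.1	0.5	-6.9	0.4	-9.2	0.5	-8.2	0.4
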