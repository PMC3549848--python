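# Published benchmark results on the standard FCC-lattice HP benchmark set:
# best and average free energies over repeated timed runs of the two reference
# local-search methods (LS-Mem, LS-Tabu) and the tabu spiral search (SS-Tabu),
# with the known lower bounds of free energy per instance.  "NA" marks results
# not reported (LS-Mem on the F90/S blocks) or an unknown lower bound (3on7).
# The F90/S/F180/R sequences are distributed by the Clote lab; the six PDB-id
# instances are HP reductions of CASP9 targets.  Sequences are external and
# not bundled; see the instance registry.
id	group	size	lb_free_energy	lsmem_best	lsmem_avg	lstabu_best	lstabu_avg	sstabu_best	sstabu_avg	time_min
F90_1	F90	90	-168	NA	NA	-164	-160	-168	-166	120
F90_2	F90	90	-168	NA	NA	-165	-158	-168	-164	120
F90_3	F90	90	-167	NA	NA	-165	-159	-167	-165	120
F90_4	F90	90	-168	NA	NA	-165	-159	-168	-165	120
F90_5	F90	90	-167	NA	NA	-165	-159	-167	-165	120
S1	S	135	-357	NA	NA	-351	-341	-355	-347	120
S2	S	151	-360	NA	NA	-355	-343	-354	-347	120
S3	S	162	-367	NA	NA	-355	-340	-359	-350	120
S4	S	164	-370	NA	NA	-354	-343	-358	-350	120
F180_1	F180	180	-378	-360	-334	-338	-327	-357	-340	300
F180_2	F180	180	-381	-362	-340	-345	-334	-359	-345	300
F180_3	F180	180	-378	-357	-343	-352	-339	-362	-353	300
R1	R	200	-384	-353	-326	-332	-318	-359	-345	300
R2	R	200	-383	-351	-330	-337	-324	-358	-346	300
R3	R	200	-385	-352	-330	-339	-323	-365	-345	300
3mse	CASP	179	-323	-278	-254	-266	-249	-289	-280	300
3mr7	CASP	189	-355	-311	-292	-301	-287	-328	-313	300
3mqz	CASP	215	-474	-415	-386	-401	-383	-420	-403	300
3no6	CASP	229	-455	-400	-375	-390	-373	-411	-391	300
3no3	CASP	258	-494	-397	-361	-388	-359	-412	-393	300
3on7	CASP	279	NA	-499	-463	-491	-461	-512	-485	300
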