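# Published ablation of the relay-restart component: best and average free
# energies of the tabu spiral search run with and without relay-restart on the
# larger benchmark instances.  "NA" marks the unknown lower bound of 3on7.
id	size	lb_free_energy	norr_best	norr_avg	rr_best	rr_avg
F180_1	180	-378	-355	-333	-357	-340
F180_2	180	-381	-358	-338	-359	-345
F180_3	180	-378	-365	-346	-362	-353
R1	200	-384	-362	-336	-359	-345
R2	200	-383	-362	-340	-358	-346
R3	200	-385	-362	-333	-365	-345
3mse	179	-323	-291	-275	-289	-280
3mr7	189	-355	-323	-309	-328	-313
3mqz	215	-474	-423	-402	-420	-403
3no6	229	-455	-412	-389	-411	-391
3no3	258	-494	-423	-386	-412	-393
3on7	279	NA	-510	-484	-512	-485
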