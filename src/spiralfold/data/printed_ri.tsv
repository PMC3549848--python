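# Published relative-improvement (RI) columns, as printed to two decimals, for
# the three comparisons: SS-Tabu average vs LS-Mem average (ls_mem), vs LS-Tabu
# average (ls_tabu), and SS-Tabu with vs without relay-restart
# (no_relay_restart).  The `rounding` column records how the printed figure
# relates to the exact RI of the corresponding energies: `half_up` (the rule
# used almost everywhere) or `truncated` (three S-block rows were printed with
# the third decimal dropped: 23.529->23.52, 37.037->37.03, 25.926->25.92).
id	comparison	printed_ri	rounding
F180_1	ls_mem	13.64	half_up
F180_2	ls_mem	12.20	half_up
F180_3	ls_mem	28.57	half_up
R1	ls_mem	32.76	half_up
R2	ls_mem	30.19	half_up
R3	ls_mem	27.27	half_up
3mse	ls_mem	37.68	half_up
3mr7	ls_mem	33.33	half_up
3mqz	ls_mem	19.32	half_up
3no6	ls_mem	20.00	half_up
3no3	ls_mem	24.06	half_up
F90_1	ls_tabu	75.00	half_up
F90_2	ls_tabu	60.00	half_up
F90_3	ls_tabu	75.00	half_up
F90_4	ls_tabu	66.67	half_up
F90_5	ls_tabu	75.00	half_up
S1	ls_tabu	37.50	half_up
S2	ls_tabu	23.52	truncated
S3	ls_tabu	37.03	truncated
S4	ls_tabu	25.92	truncated
F180_1	ls_tabu	25.49	half_up
F180_2	ls_tabu	23.40	half_up
F180_3	ls_tabu	35.90	half_up
R1	ls_tabu	40.91	half_up
R2	ls_tabu	37.29	half_up
R3	ls_tabu	35.48	half_up
3mse	ls_tabu	41.89	half_up
3mr7	ls_tabu	38.24	half_up
3mqz	ls_tabu	21.98	half_up
3no6	ls_tabu	21.95	half_up
3no3	ls_tabu	25.19	half_up
F180_1	no_relay_restart	15.56	half_up
F180_2	no_relay_restart	16.28	half_up
F180_3	no_relay_restart	21.88	half_up
R1	no_relay_restart	18.75	half_up
R2	no_relay_restart	13.95	half_up
R3	no_relay_restart	23.08	half_up
3mse	no_relay_restart	10.42	half_up
3mr7	no_relay_restart	8.70	half_up
3mqz	no_relay_restart	1.39	half_up
3no6	no_relay_restart	3.03	half_up
3no3	no_relay_restart	6.48	half_up
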