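name	formula	mw	density	density_temp_C	alpha	beta	pi_star	dD	dP	dH	nile_red_lambda_max
DFX	C7H10O5	174.15	1.35	50	0.00	0.82	0.92	17.9	9.0	7.6	543
DPX	C11H18O5	230.26	1.17	50	0.00	0.63	0.68	16.4	6.1	4.5	536
DBX	C13H22O5	258.31	1.15	50	0.00	0.56	0.65	16.3	5.2	3.8	534
DIBX	C13H22O5	258.31	1.11	50	0.00	0.51	0.63	16.2	4.9	3.2	535
DMF	C3H7NO	73.09	0.94	25	0.00	0.69	0.88	17.4	13.7	11.1	541
NMP	C5H9NO	99.13	1.03	25	0.00	0.75	0.90	18.0	12.3	7.2	541
THF	C4H8O	72.11	0.89	25	0.00	0.55	0.58	16.8	5.7	8.0	528
1,4-dioxane	C4H8O2	88.11	1.03	25	0.00	0.37	0.55	17.3	4.3	8.4	516
DPE	C12H10O	170.21	1.07	25	0.00	0.13	0.66	19.4	3.4	4.0
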