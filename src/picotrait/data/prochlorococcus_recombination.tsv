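region	functional_group	n_sequences	alignment_length	kappa	delta	nu	R_over_theta	published_rho_over_theta	published_r_over_m
nirA-moaA	nitrate	33	11428	3.32	4202	0.012	0.68	1.36	34.0
polA_region	core_flanking	19	11554	3.72	8035	0.020	0.20	0.41	33.2
moaB-narB	nitrate	17	11985	2.91	435	0.021	1.78	3.57	16.5
pyrG_region	core_flanking	15	10080	2.81	964	0.029	2.17	4.34	59.7
ppk_region	core_flanking	15	11918	3.19	1056	0.031	0.93	1.85	30.3
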