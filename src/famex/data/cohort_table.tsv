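individual_id	family_id	sex	age_last_exam	age_tremor_onset	age_seizure_onset	nanopore_blood_n_p	nanopore_blood_total_kb	nanopore_blood_5p_kb	nanopore_blood_mid_kb	combing_blood_n_p	combing_blood_total_kb	combing_blood_5p_kb	combing_blood_mid_kb	combing_blood_3p_kb	combing_fibro_n_p	combing_fibro_total_kb	combing_fibro_5p_kb	combing_fibro_mid_kb	combing_fibro_3p_kb
1-IV-6	1	M	58	30	25	4	4.73	2.95	1.78	71	4.62	0.88	2.82	0.92	10	6.93	0.13	4.56	2.24
1-IV-8	1	M	53	52	46	1	5.13	2.93	2.21	58	5.06	2.33	2.28	0.46	11	4.65	1.04	2.63	0.97
1-IV-9	1	M	61	25	NA	1	4.16	3.08	1.08	25	3.34	0.57	2.10	0.67	41	3.82	0.02	2.73	1.08
1-IV-11	1	F	60	30	32	2	5.67	3.00	2.67	29	4.92	1.66	2.86	0.40	13	4.12	0.50	2.04	1.59
2-IV-9	2	M	60	40	18	4	NA	NA	>5	219	14.07	2.37	10.37	1.32	NA	NA	NA	NA	NA
2-IV-16	2	M	71	14	30	1	5.40	4.60	0.80	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
2-IV-18	2	F	67	NA	30	NA	NA	NA	NA	50	5.72	3.47	1.99	0.27	NA	NA	NA	NA	NA
2-V-9	2	M	28	NA	17	NA	NA	NA	NA	54	13.33	1.99	10.04	1.31	NA	NA	NA	NA	NA
2-V-20	2	F	39	14	NA	NA	NA	NA	NA	30	6.16	2.81	2.93	0.41	NA	NA	NA	NA	NA
2-V-22	2	M	44	28	30	NA	NA	NA	NA	38	7.55	3.04	3.60	0.90	NA	NA	NA	NA	NA
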