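feature_id	log2fc	p_raw	p_adj	direction
hsa-miR-486-5p	10.6609	1.38E-20	1.19E-19	up
hsa-miR-182-5p	8.9478	4.55E-26	4.63E-25	up
hsa-miR-10a-5p	6.1349	3.60E-09	1.19E-08	up
hsa-miR-183-5p	5.7463	2.02E-15	1.19E-14	up
hsa-miR-22-3p	5.5587	7.96E-17	4.95E-16	up
hsa-miR-19b-3p	4.7807	3.32E-13	1.43E-12	up
hsa-miR-186-5p	4.3815	3.43E-19	2.56E-18	up
hsa-miR-92b-3p	4.0673	3.01E-12	1.16E-11	up
hsa-miR-769-5p	3.9268	7.24E-12	2.70E-11	up
hsa-miR-27b-3p	3.8964	4.25E-14	2.07E-13	up
hsa-miR-30b-5p	3.5192	9.55E-11	3.45E-10	up
hsa-miR-146b-5p	3.4102	8.07E-10	2.74E-09	up
hsa-miR-532-5p	3.1493	2.26E-10	7.93E-10	up
hsa-miR-660-5p	3.1183	6.35E-09	2.03E-08	up
hsa-miR-26a-5p	3.0639	2.38E-07	6.65E-07	up
hsa-miR-130a-3p	3.0018	3.50E-05	7.13E-05	up
hsa-miR-21-3p	2.7137	2.29E-06	5.58E-06	up
hsa-miR-92a-3p	2.6837	2.11E-08	6.58E-08	up
hsa-miR-148a-3p	2.6221	2.61E-07	7.14E-07	up
hsa-miR-99b-5p	2.4566	1.97E-04	3.74E-04	up
hsa-miR-3615	2.2328	1.23E-05	2.65E-05	up
hsa-miR-340-5p	2.1321	2.30E-04	4.30E-04	up
hsa-miR-423-5p	-6.82082	6.92E-38	2.59E-36	down
hsa-miR-331-3p	-6.22424	4.78E-28	6.70E-27	down
hsa-miR-222-3p	-5.76142	3.31E-29	6.18E-28	down
hsa-miR-140-3p	-5.67778	1.03E-52	1.16E-50	down
hsa-let-7d-5p	-5.54828	1.29E-27	1.61E-26	down
hsa-miR-320a	-5.12011	3.82E-38	2.14E-36	down
hsa-miR-29a-3p	-4.80203	4.01E-36	1.12E-34	down
hsa-let-7g-5p	-4.78494	3.71E-18	2.46E-17	down
hsa-let-7f-5p	-4.52246	4.60E-23	4.29E-22	down
hsa-miR-221-3p	-4.50804	1.18E-33	2.64E-32	down
hsa-let-7e-5p	-4.44258	6.34E-27	7.10E-26	down
hsa-let-7b-5p	-3.90908	2.16E-15	1.21E-14	down
hsa-miR-28-5p	-3.85689	6.16E-29	9.86E-28	down
hsa-let-7a-5p	-3.79827	1.52E-20	1.22E-19	down
hsa-miR-1260a	-3.32632	7.61E-14	3.55E-13	down
hsa-miR-103a-3p	-3.23483	3.74E-18	2.46E-17	down
hsa-miR-1260b	-3.16842	1.42E-12	5.91E-12	down
hsa-miR-30e-3p	-3.00521	8.00E-15	4.27E-14	down
hsa-let-7c	-2.98489	3.79E-14	1.93E-13	down
hsa-miR-29c-3p	-2.90631	2.48E-13	1.11E-12	down
hsa-miR-107	-2.89683	2.00E-12	8.00E-12	down
hsa-miR-1275	-2.52971	1.30E-05	2.74E-05	down
hsa-miR-15b-5p	-2.17524	4.93E-08	1.45E-07	down
hsa-miR-423-3p	-2.15549	7.20E-07	1.92E-06	down
hsa-miR-378i	-2.13256	1.86E-06	4.64E-06	down
hsa-miR-155-5p	-2.07727	8.29E-06	1.82E-05	down
hsa-miR-21-5p	-2.02446	4.01E-08	1.22E-07	down
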