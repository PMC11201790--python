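marker	Na	Ne	Ho	He	I	H	PIC
SSR61	9.00	4.39	0.20	0.80	1.78	0.77	0.75
SSR114	8.00	3.37	0.29	0.71	1.46	0.70	0.66
SSR139	3.00	2.01	0.49	0.51	0.85	0.50	0.44
SSR613	5.00	2.57	0.38	0.62	1.18	0.61	0.56
SSR42749	5.00	2.43	0.40	0.60	1.13	0.59	0.54
SSR53846	2.00	1.99	0.49	0.51	0.69	0.50	0.37
SSR65750	2.00	1.23	0.81	0.19	0.33	0.18	0.17
SSR69944	3.00	2.14	0.46	0.54	0.82	0.53	0.42
SSR73677	4.00	2.12	0.46	0.54	0.93	0.53	0.46
SSR76953	2.00	1.92	0.51	0.49	0.67	0.48	0.36
SSR93286	2.00	1.98	0.50	0.50	0.69	0.50	0.37
SSR108420	3.00	1.82	0.54	0.46	0.74	0.45	0.38
SSR111053	2.00	1.99	0.49	0.51	0.69	0.50	0.37
SSR151039	4.00	3.08	0.31	0.69	1.25	0.68	0.63
SSR151215	4.00	1.49	0.66	0.34	0.66	0.33	0.31
SSR159645	2.00	2.00	0.49	0.51	0.69	0.50	0.37
SSR160502	2.00	2.00	0.49	0.51	0.69	0.50	0.37
SSR161040	4.00	2.18	0.45	0.55	0.87	0.54	0.44
SSR185330	2.00	1.06	0.94	0.06	0.14	0.06	0.06
SSR212641	2.00	2.00	0.49	0.51	0.69	0.50	0.37
SSR216561	3.00	2.98	0.33	0.67	1.10	0.66	0.59
SSR243677	2.00	1.08	0.92	0.08	0.17	0.08	0.07
SSR243820	2.00	1.99	0.49	0.51	0.69	0.50	0.37
SSR247694	2.00	1.03	0.97	0.03	0.08	0.03	0.03
SSR261825	2.00	1.13	0.88	0.12	0.23	0.12	0.11
SSR267344	2.00	1.06	0.94	0.06	0.13	0.06	0.05
SSR267366	7.00	4.81	0.20	0.80	1.67	0.79	0.76
SSR282418	7.00	4.38	0.21	0.79	1.64	0.77	0.74
SSR292741	3.00	1.14	0.88	0.12	0.28	0.12	0.12
SSR293332	2.00	2.00	0.49	0.51	0.69	0.50	0.37
SSR304785	5.00	1.78	0.55	0.45	0.92	0.44	0.42
SSR307134	2.00	1.42	0.70	0.30	0.47	0.30	0.25
SSR313484	5.00	4.30	0.22	0.78	1.53	0.77	0.73
SSR318481	8.00	5.23	0.17	0.83	1.80	0.81	0.78
SSR326475	7.00	2.83	0.34	0.66	1.26	0.65	0.58
SSR327195	3.00	1.81	0.55	0.45	0.69	0.45	0.36
SSR327794	4.00	2.63	0.37	0.63	1.13	0.62	0.56
SSR332709	4.00	2.25	0.44	0.57	0.91	0.56	0.46
SSR345052	2.00	1.06	0.94	0.06	0.13	0.06	0.06
SSR349227	4.00	2.94	0.33	0.67	1.19	0.66	0.60
SSR353503	2.00	1.84	0.54	0.46	0.65	0.46	0.35
SSR353506	5.00	2.65	0.37	0.63	1.16	0.62	0.55
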