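residue	PP1	PP2	PP3	KF1	KF2	KF3	KF4	KF5	KF6	KF7	KF8	KF9	KF10	Z1	Z2	Z3	Z4	Z5	F1	F2	F3	F4	F5	F6	T1	T2	T3	T4	T5	VHSE1	VHSE2	VHSE3	VHSE4	VHSE5	VHSE6	VHSE7	VHSE8	ProtFP1	ProtFP2	ProtFP3	ProtFP4	ProtFP5	ProtFP6	ProtFP7	ProtFP8	ST1	ST2	ST3	ST4	ST5	ST6	ST7	ST8	BLOSUM1	BLOSUM2	BLOSUM3	BLOSUM4	BLOSUM5	BLOSUM6	BLOSUM7	BLOSUM8	BLOSUM9	BLOSUM10	MSWHIM1	MSWHIM2	MSWHIM3
A	-0.96	-0.76	0.31	-1.56	-1.67	-0.97	-0.27	-0.93	-0.78	-0.2	-0.08	0.21	-0.48	0.24	-2.32	0.6	-0.14	1.3	0.206	0.215	-0.681	-0.601	-0.446	-0.409	-9.11	-1.63	0.63	1.04	2.26	0.15	-1.11	-1.35	-0.92	0.02	-0.91	0.36	-0.48	0.92	-2.18	-2.53	1.66	0.21	0.64	-0.51	0.74	-1.552	-0.791	-0.627	0.237	-0.461	-2.229	0.283	1.221	0.57	3.37	-3.66	2.34	-1.07	-0.4	1.23	-2.32	-2.01	1.31	-0.73	0.2	-0.62
R	0.8	0.63	0.99	0.22	1.27	1.37	1.87	-1.7	0.46	0.92	-0.39	0.23	0.93	3.52	2.5	-3.5	1.99	-0.17	-0.475	0.246	0.619	0.52	0.381	0.916	0.23	3.89	-1.16	-0.39	-0.06	-1.47	1.45	1.24	1.27	1.55	1.47	1.3	0.83	-2.55	3.03	0.99	0.69	0.25	0.29	1.13	0.29	-0.059	0.731	-0.013	-0.096	-0.253	0.3	1.256	0.854	-2.8	0.31	2.84	0.25	0.2	-0.37	3.81	0.98	2.43	-0.99	-0.22	0.27	1
N	0.82	-0.57	0.02	1.14	-0.07	-0.12	0.81	0.18	0.37	-0.09	1.23	1.1	-1.73	3.05	1.62	1.04	-1.15	1.61	-0.724	-0.141	-0.282	0.515	0.149	0.061	-4.62	0.66	1.16	-0.22	0.93	-0.99	0	-0.37	0.69	-0.55	0.85	0.73	-0.8	-2.06	-0.17	-0.48	-1.66	0.41	-0.97	0.21	0.33	-0.888	-0.057	-0.651	-0.214	0.917	0.164	-0.14	-0.166	-2.02	-1.92	0.04	-0.65	1.61	2.08	0.4	-2.47	-0.07	1.32	0.14	0.2	-0.66
D	1	-0.89	-1	0.58	-0.22	-1.58	0.81	-0.92	0.15	-1.52	0.47	0.76	0.7	3.98	0.93	1.93	-2.46	0.75	-0.79	-0.291	-0.27	0.394	0.396	-0.107	-4.65	0.75	1.39	-0.4	1.05	-1.15	0.67	-0.41	-0.01	-2.68	1.31	0.03	0.56	-2.92	-0.44	-0.79	-1.79	-1.12	-0.39	-0.23	-0.29	-0.907	-0.054	-0.781	-0.248	1.12	0.101	-0.245	-0.075	-2.46	-0.66	-0.57	0.14	0.75	0.24	-5.15	-1.17	0.73	1.5	0.11	-1	-0.96
C	-0.55	-0.47	0.19	0.12	-0.89	0.45	-1.05	-0.71	2.41	1.52	-0.69	1.13	1.1	0.84	-1.67	3.71	0.18	-2.65	0.766	-0.359	-0.221	-0.422	0.192	-0.199	-7.35	-0.86	-0.33	0.8	0.98	0.18	-1.67	-0.46	-0.21	0	1.2	-1.61	-0.19	1.75	-1.08	2.69	-1.54	1.04	2.11	0.32	-0.99	-1.276	-0.401	0.134	0.859	-0.196	-0.72	0.639	-0.857	2.66	-1.52	-3.29	-3.77	2.96	-2.23	0.44	-3.49	2.22	-3.78	-0.66	0.26	-0.27
Q	0.78	-0.3	-0.38	-0.47	0.24	0.07	1.1	1.1	0.59	0.84	-0.71	-0.03	-2.33	1.75	0.5	-1.44	-1.34	0.66	-0.458	0.199	0.107	0.541	0.042	0.329	-3	1.72	0.28	-0.39	0.33	-0.96	0.12	0.18	0.16	0.09	0.42	-0.2	-0.41	-1.73	1.18	-0.29	-0.41	0.32	0.35	-0.52	0.66	-0.622	0.228	-0.193	-0.105	0.418	0.474	0.172	0.408	-2.54	1.82	-0.82	-1.85	0.09	0.6	0.25	2.11	-1.92	-1.67	0.3	1	-0.3
E	0.94	-0.54	-0.99	-1.45	0.19	-1.61	1.17	-1.31	0.4	0.04	0.38	-0.35	-0.12	3.11	0.26	-0.11	-3.04	-0.25	-0.657	0.171	-0.03	0.479	0.545	0.061	-3.03	1.82	0.51	-0.58	0.43	-1.18	0.4	0.1	0.36	-2.16	-0.17	0.91	0.02	-2.84	0.74	-0.52	-0.41	-1.99	0.25	0.13	0.15	-0.629	0.39	-0.38	-0.366	0.635	0.514	0.175	0.367	-3.08	3.45	0.05	0.62	-0.49	0	-5.66	-0.11	1.04	-0.76	0.24	-0.39	-0.04
G	0	-1	0.49	1.46	-1.96	-0.23	-0.16	0.1	-0.11	1.32	2.36	-1.66	0.46	2.05	-4.06	0.36	-0.82	-0.38	-0.493	-0.684	-0.95	-0.359	-0.279	-0.184	-10.61	-1.21	-0.12	0.75	3.25	-0.2	-1.53	-2.63	2.28	-0.53	-1.18	2.01	-1.34	-1.21	-3.25	-2.55	-1.33	0.55	-0.67	-0.97	-0.95	-1.844	-0.018	-0.184	0.573	-0.728	-3.317	0.166	2.522	0.15	-3.49	-2.97	2.06	0.7	2.47	0.41	1.62	-0.47	-1.88	-0.31	-0.28	-0.75
H	0.67	-0.11	0.37	-0.41	0.52	-0.28	0.28	1.61	1.01	-1.85	0.47	1.13	1.63	2.47	1.95	0.26	3.9	0.09	0.096	-0.081	0.342	0.161	-0.064	0.376	-1.01	-1.31	0.01	-1.81	-0.21	-0.43	-0.25	0.37	0.19	0.51	1.28	0.93	0.65	-0.86	1.03	0.73	-1.18	0.78	-0.47	0.59	-0.44	-0.225	0.361	0.079	-1.037	0.568	0.273	1.208	-0.001	-0.39	1	-0.63	-3.49	0.05	0.41	1.61	-0.6	3.55	1.52	0.84	0.67	-0.78
I	-0.94	-0.05	-0.18	-0.73	-0.16	1.79	-0.77	-0.54	0.03	-0.83	0.51	0.66	-1.78	-3.89	-1.73	-1.71	-0.84	0.26	1	0.274	0.143	-0.683	-0.255	-0.378	-4.25	-0.28	-0.15	1.4	-0.21	1.27	-0.14	0.3	-1.8	0.3	-1.61	-0.16	-0.13	3.19	-0.66	0.85	1.55	0.21	-0.32	0.2	0.35	-0.785	-1.01	-0.349	1.097	-0.267	-0.259	0.024	0.084	3.1	0.37	0.26	1.04	-0.05	-1.18	-0.21	3.45	0.86	1.98	-0.91	0.83	-0.25
L	-0.9	0.03	-0.24	-1.04	0	-0.24	-1.1	-0.55	-2.05	0.96	-0.76	0.45	0.93	-4.28	-1.3	-1.49	-0.72	0.84	0.862	0.46	0.084	-0.654	-0.218	-0.32	-4.38	0.28	-0.49	1.45	0.02	1.36	0.07	0.26	-0.8	0.22	-1.37	0.08	-0.62	2.91	0.11	0.19	1.53	0.21	-0.55	-0.32	0.38	-0.826	-0.379	0.038	-0.059	-0.625	1.022	-1.524	0.693	2.72	1.88	1.17	0.82	-1.18	-2.37	-1.34	0.64	-1.2	0.67	-0.74	0.72	-0.16
K	0.6	0.1	1	-0.34	0.82	-0.23	1.7	1.54	-1.62	1.15	-0.08	-0.48	0.6	2.29	0.89	-2.49	1.49	0.31	-0.637	0.302	0.348	0.322	0.685	0.514	-2.59	2.34	-1.69	0.41	-0.21	-1.17	0.7	0.7	0.8	1.64	0.67	1.63	0.13	-2.36	2.51	0.04	1.39	0.85	-0.2	-0.59	-0.36	-0.504	0.245	0.297	-0.065	-0.387	1.011	0.525	0.553	-3.89	1.47	1.95	1.17	0.53	0.1	4.01	-0.01	-0.26	-1.66	-0.51	0.08	0.7
M	-0.82	0.03	-0.08	-1.4	0.18	-0.42	-0.73	2	1.52	0.26	0.11	-1.27	0.27	-2.85	-0.22	0.47	1.94	-0.98	0.625	0.379	0.164	-0.301	-0.201	-0.044	-4.08	0.98	-2.34	1.64	-0.79	1.01	-0.53	0.43	0	0.23	0.1	-0.86	-0.68	2.48	0.63	0.79	0.28	-0.54	0.78	-0.54	-0.37	-0.693	0.498	0.658	0.457	-0.231	1.064	0.248	-0.778	2.67	2.41	-0.1	0.49	-0.52	-0.93	0.11	1.33	-1.87	0.86	-0.7	1	-0.32
F	-0.85	0.48	-0.58	-0.21	0.98	-0.36	-1.43	0.22	-0.81	0.67	1.1	1.71	-0.44	-4.22	1.94	1.06	0.54	-0.62	0.867	0.214	0.538	-0.565	-0.305	-0.213	0.49	-0.94	-0.63	-1.27	-0.44	1.52	0.61	0.96	-0.16	0.25	0.28	-1.33	-0.2	3.03	0.68	1.17	-0.75	-0.06	-0.46	-0.75	0.11	-0.019	-0.24	0.76	0.341	-0.441	0.222	-0.674	-0.459	3.12	0.68	2.4	-0.35	-0.88	1.62	-0.15	-0.41	4.2	0.73	0.76	0.85	-0.34
P	-0.81	-0.4	-0.07	2.06	-0.33	-1.15	-0.75	0.88	-0.45	0.3	-2.3	0.74	-0.28	-1.66	0.27	1.84	0.7	2	-0.271	-1	-0.42	0.211	0.048	-0.271	-5.11	-3.54	-0.53	-0.36	-0.29	0.22	-0.17	-0.5	0.05	-0.01	-1.34	-0.19	3.56	-1.12	-1.79	-1.35	-0.66	1.09	0.85	1.83	0.45	-1.049	-0.407	-0.067	-0.066	-0.813	-0.89	0.021	-0.894	-0.58	-4.33	-0.02	-0.21	-2.31	-1.82	-0.12	-1.18	0	-0.66	-0.43	0.73	-0.6
S	0.41	-0.82	0.57	0.81	-1.08	0.16	0.42	-0.21	-0.43	-1.89	-1.15	-0.97	-0.23	2.39	-1.07	1.15	-1.39	0.67	-0.472	-0.249	-0.598	0.188	-0.038	-0.102	-7.44	-0.65	0.68	-0.17	1.58	-0.67	-0.86	-1.07	-0.41	-0.32	0.27	-0.64	0.11	-1.42	-1.65	-1.51	-0.91	0.42	-0.25	0.31	0.18	-1.343	-0.311	-0.917	-0.049	0.549	-1.533	0.166	0.28	-1.1	-2.05	-2.19	1.36	1.78	-3.36	1.39	-1.21	-2.83	0.39	-0.8	0.61	-1
T	0.4	-0.64	0.37	0.26	-0.7	1.21	0.63	-0.1	0.21	0.24	-1.15	-0.56	0.19	0.75	-2.18	-1.12	-1.46	-0.4	-0.249	-0.222	-0.376	-0.005	-0.119	-0.128	-5.97	-0.62	1.11	0.31	0.95	-0.34	-0.51	-0.55	-1.06	-0.06	-0.01	-0.79	0.39	-0.66	-1.28	-1.18	0.24	0.32	-0.45	0.12	0.74	-1.061	-0.928	-0.911	-0.063	0.538	-0.775	-0.147	-0.717	-0.65	-1.6	-1.39	0.63	1.35	-2.45	-0.65	3.43	0.34	0.24	-0.58	0.85	-0.89
W	-0.56	1	-0.47	0.3	2.1	-0.72	-1.57	-1.16	0.57	-0.48	-0.4	-2.3	-0.6	-4.36	3.94	0.59	3.44	-1.59	0.697	0.145	1	-0.638	-0.246	0.063	5.73	-2.67	-0.07	-1.96	-0.54	1.5	2.06	1.79	0.75	0.75	-0.13	-1.01	-0.85	2.93	2.05	2.38	-1.6	-1.02	-0.77	0.67	-0.1	0.853	0.039	0.26	-1.163	0.16	-0.202	1.01	0.195	1.89	-0.09	4.21	-2.77	0.72	0.86	-1.07	-1.66	-5.87	-0.66	1	0.98	-0.47
Y	-0.31	0.42	-0.2	1.38	1.48	0.8	-0.56	0	-0.68	-0.31	1.03	-0.05	0.53	-2.54	2.44	0.43	0.04	-1.47	0.511	0.048	0.666	-0.355	-0.274	0.003	2.08	-0.47	0.07	-1.67	-0.35	0.61	1.6	1.17	0.73	0.53	0.25	-0.96	-0.52	1.55	1.85	1.5	-1.34	-0.35	-0.86	-0.22	-0.5	0.308	0.569	1.1	-0.464	0.523	-0.226	0.344	-0.984	0.79	-2.62	4.11	-0.63	1.89	-0.53	-1.3	1.31	-0.56	-0.95	0.97	0.66	-0.16
V	-0.96	-0.35	-0.19	-0.74	-0.71	2.04	-0.4	0.5	-0.81	-1.07	0.06	-0.46	0.65	-2.59	-2.64	-1.54	-0.85	-0.02	0.942	0.136	-0.169	-0.661	-0.284	-0.397	-5.87	-0.94	0.28	1.1	0.48	0.76	-0.92	-0.17	-1.91	0.22	-1.4	-0.24	-0.03	2.6	-1.32	-0.13	1.64	0.38	-0.27	0.21	0.26	-1.133	-0.893	-0.325	0.303	-0.561	-0.175	-0.02	-0.311	2.64	0.03	-0.67	2.34	0.64	-2.01	-0.33	3.93	-0.21	1.27	-1	0.79	-0.58
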