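# ref_map_version: synthetic-snapshot-1.0
id	description
EC:2.18.15.16	ribose isomerase
EC:6.17.6.10	NADH permease
EC:5.4.2.21	maltose dehydrogenase
EC:5.6.8.38	alanine synthase
EC:4.1.9.16	pyruvate mutase
EC:6.10.7.78	lactate transporter
EC:6.8.1.86	sulfate decarboxylase
EC:1.15.12.59	succinate reductase
EC:5.14.6.12	maltose reductase
EC:4.4.17.76	maltose ligase
EC:3.1.1.32	xylose oxidase
EC:3.1.12.68	pyruvate kinase
EC:2.9.3.75	malate kinase
EC:3.13.16.65	serine transporter
EC:1.17.16.59	pyruvate thioesterase
EC:6.8.7.74	glutamate dehydrogenase
EC:2.2.1.2	nitrate phosphatase
EC:2.12.12.77	glucose thioesterase
EC:5.19.19.85	fructose ligase
EC:2.18.4.20	pyruvate synthase
EC:5.3.3.55	malate transferase
EC:4.19.8.6	succinate kinase
EC:1.5.15.41	citrate phosphatase
EC:1.10.15.18	fructose decarboxylase
EC:1.11.1.33	malate isomerase
EC:3.1.15.21	maltose aminotransferase
EC:3.11.15.1	nitrate mutase
EC:5.12.2.9	acetyl-CoA ligase
EC:5.1.13.70	xylose epimerase
EC:3.12.6.75	glucose aldolase
EC:1.6.12.17	malate mutase
EC:6.2.4.8	glutamate phosphatase
EC:1.2.13.72	NADH isomerase
EC:6.7.15.60	nitrate reductase
EC:4.16.14.55	fructose isomerase
EC:2.12.14.72	serine racemase
EC:3.4.12.87	malate mutase
EC:6.10.10.25	maltose reductase
EC:1.2.2.57	glucose permease
EC:5.17.19.19	fructose kinase
EC:6.17.2.14	fructose decarboxylase
EC:3.12.3.54	malate aldolase
EC:6.9.13.65	sulfate thioesterase
EC:2.17.10.60	glutamate permease
EC:1.16.14.96	nitrate oxidase
EC:1.2.9.70	alanine transferase
EC:1.15.1.76	alanine permease
EC:6.15.5.7	succinate reductase
EC:4.9.19.61	NADH kinase
EC:4.5.11.58	alanine hydrolase
EC:2.16.17.95	fructose hydrolase
EC:2.10.15.38	ribose kinase
EC:1.4.19.94	alanine transferase
EC:3.11.7.52	sulfate synthase
EC:5.16.8.79	glycerol carboxylase
EC:2.11.7.48	sulfate hydrolase
EC:3.8.15.66	NADH ligase
EC:6.19.12.85	pyruvate phosphatase
EC:1.17.18.83	pyruvate phosphatase
EC:5.4.16.51	xylose reductase
EC:6.15.2.23	sulfate isomerase
EC:6.18.16.25	malate decarboxylase
EC:4.12.9.32	pyruvate kinase
EC:2.14.4.19	maltose ligase
EC:1.7.15.82	nitrate thioesterase
EC:4.12.2.97	fructose aldolase
EC:4.1.17.65	lactate reductase
EC:1.12.2.86	maltose mutase
EC:6.7.10.93	pyruvate transporter
EC:5.19.13.3	xylose aminotransferase
EC:2.6.19.5	pyruvate aldolase
EC:6.18.5.32	succinate dehydrogenase
EC:1.18.4.10	nitrate transporter
EC:4.9.9.63	glutamate mutase
EC:6.10.4.69	fructose dehydrogenase
EC:2.7.7.31	xylose synthase
EC:5.18.8.19	ribose dehydrogenase
EC:3.3.7.19	glutamate aldolase
EC:2.12.5.31	alanine transporter
EC:5.16.13.1	urea aminotransferase
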