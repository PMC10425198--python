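# ref_map_version: synthetic-snapshot-1.0
id	description
PWY-1000	glucose oxidation (synthetic snapshot)
PWY-1001	succinate oxidation (synthetic snapshot)
PWY-1002	pyruvate degradation (synthetic snapshot)
PWY-1003	fructose fermentation (synthetic snapshot)
PWY-1004	fructose fermentation (synthetic snapshot)
PWY-1005	maltose oxidation (synthetic snapshot)
PWY-1006	urea biosynthesis (synthetic snapshot)
PWY-1007	xylose degradation (synthetic snapshot)
PWY-1008	histidine fermentation (synthetic snapshot)
PWY-1009	sulfate biosynthesis (synthetic snapshot)
PWY-1010	malate oxidation (synthetic snapshot)
PWY-1011	lactate degradation (synthetic snapshot)
PWY-1012	fructose oxidation (synthetic snapshot)
PWY-1013	lactate biosynthesis (synthetic snapshot)
PWY-1014	pyruvate biosynthesis (synthetic snapshot)
PWY-1015	glycerol degradation (synthetic snapshot)
PWY-1016	xylose biosynthesis (synthetic snapshot)
PWY-1017	NADH degradation (synthetic snapshot)
PWY-1018	lactate oxidation (synthetic snapshot)
PWY-1019	nitrate fermentation (synthetic snapshot)
PWY-1020	succinate fermentation (synthetic snapshot)
PWY-1021	pyruvate oxidation (synthetic snapshot)
PWY-1022	sulfate fermentation (synthetic snapshot)
PWY-1023	urea fermentation (synthetic snapshot)
PWY-1024	fructose biosynthesis (synthetic snapshot)
PWY-1025	pyruvate degradation (synthetic snapshot)
PWY-1026	sulfate degradation (synthetic snapshot)
PWY-1027	NADH degradation (synthetic snapshot)
PWY-1028	histidine biosynthesis (synthetic snapshot)
PWY-1029	maltose fermentation (synthetic snapshot)
PWY-1030	histidine degradation (synthetic snapshot)
PWY-1031	glucose biosynthesis (synthetic snapshot)
PWY-1032	glucose degradation (synthetic snapshot)
PWY-1033	ribose fermentation (synthetic snapshot)
PWY-1034	NADH biosynthesis (synthetic snapshot)
PWY-1035	glucose biosynthesis (synthetic snapshot)
PWY-1036	glycerol degradation (synthetic snapshot)
PWY-1037	NADH fermentation (synthetic snapshot)
PWY-1038	ribose biosynthesis (synthetic snapshot)
PWY-1039	maltose biosynthesis (synthetic snapshot)
PWY-1040	serine degradation (synthetic snapshot)
PWY-1041	urea degradation (synthetic snapshot)
PWY-1042	nitrate degradation (synthetic snapshot)
PWY-1043	sulfate fermentation (synthetic snapshot)
PWY-1044	malate degradation (synthetic snapshot)
PWY-1045	glucose biosynthesis (synthetic snapshot)
PWY-1046	lactate degradation (synthetic snapshot)
PWY-1047	succinate oxidation (synthetic snapshot)
PWY-1048	NADH biosynthesis (synthetic snapshot)
PWY-1049	histidine biosynthesis (synthetic snapshot)
PWY-1050	maltose oxidation (synthetic snapshot)
PWY-1051	glucose fermentation (synthetic snapshot)
PWY-1052	alanine biosynthesis (synthetic snapshot)
PWY-1053	citrate degradation (synthetic snapshot)
PWY-1054	maltose degradation (synthetic snapshot)
PWY-1055	citrate fermentation (synthetic snapshot)
PWY-1056	succinate biosynthesis (synthetic snapshot)
PWY-1057	citrate degradation (synthetic snapshot)
PWY-1058	NADH degradation (synthetic snapshot)
PWY-1059	maltose degradation (synthetic snapshot)
PWY-1060	urea fermentation (synthetic snapshot)
PWY-1061	pyruvate biosynthesis (synthetic snapshot)
PWY-1062	acetyl-CoA degradation (synthetic snapshot)
PWY-1063	fructose biosynthesis (synthetic snapshot)
PWY-1064	urea oxidation (synthetic snapshot)
PWY-1065	glutamate fermentation (synthetic snapshot)
PWY-1066	alanine fermentation (synthetic snapshot)
PWY-1067	xylose fermentation (synthetic snapshot)
PWY-1068	citrate biosynthesis (synthetic snapshot)
PWY-1069	glycerol degradation (synthetic snapshot)
PWY-1070	glutamate degradation (synthetic snapshot)
PWY-1071	ribose fermentation (synthetic snapshot)
PWY-1072	histidine oxidation (synthetic snapshot)
PWY-1073	malate degradation (synthetic snapshot)
PWY-1074	xylose oxidation (synthetic snapshot)
PWY-1075	glutamate biosynthesis (synthetic snapshot)
PWY-1076	maltose oxidation (synthetic snapshot)
PWY-1077	ribose biosynthesis (synthetic snapshot)
PWY-1078	succinate biosynthesis (synthetic snapshot)
PWY-1079	alanine fermentation (synthetic snapshot)
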