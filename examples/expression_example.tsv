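	H0002_1	H0002_2	H0007_1	H0007_2	H0008_1	H0008_2
DNMT1	1006.3023641434063	969.3357148580543	426.43684966614177	408.0695437075864	939.024241325879	1018.0182726174613
GCLC	993.4206190657502	1002.0671428764288	1070.6656194011148	989.6021841090103	1078.5838628152783	941.4084042079494
GPX4	1032.5186889529289	890.3158605308967	1257.4995812937082	1289.6978717883378	1390.434146389905	1299.710694247974
GSR	1005.2554940736034	989.1267901719139	1017.7196972136954	1027.393898913808	1039.813309622972	1033.347218143676
GSS	973.5883029365393	939.6416824414706	871.8165610373763	842.3199913544632	1276.760805012628	1181.4397887472956
GSTA4	1018.232690538416	964.0708267711842	1004.7087323772586	1017.916147678358	984.4360460057223	1019.9399695045083
GSTM1	1067.3290441970908	973.1705164086239	963.5298994116941	967.8569070296992	1075.5751401750772	1021.7121205456858
GSTM2	1048.4621713555152	984.3191089386004	954.9870451945673	993.544291471532	1102.9095580314	1035.392326454164
GSTT1	965.4462977949355	1020.7816738912021	977.3875748398336	1039.9517391259362	1094.2022057661281	942.5475173198028
OPLAH	938.726055902632	1053.4738521488919	1011.0636387306308	1077.4799669123208	1986.3338128961402	1799.5056879349556
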