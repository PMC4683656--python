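name	td	TB9Sb	PI	Telo2_1	Iso3	Telo2_2	cenh3	pcr
CRM2-ACC-CCA-AGA-ATA-196	TD1	+	-	-	-	-	0	0
CRM2-CCA-375	TD2	+	-	-	-	-	0	0
CRM2-CCC-280	TD3	+	-	-	-	-	0	0
CRM2-CCC-TCC-342	TD4	+	-	-	-	-	0	0
CRM2-GGA-GAC-405	TD5	+	-	-	-	-	0	0
CRM2-TAT-GAT-CTT-173	TD6	+	+	-	-	-	0	0
CRM2-ATA-CCA-342	TD7	+	+	+	-	-	1	1
CRM2-TCC-310	TD8	+	+	+	+	-	0	1
CRM2-TCT-209	TD9	+	+	+	+	-	1	0
CRM2-AGA-214	TD10	+	+	+	+	+	1	1
CRM2-CTA-CTG-GTA-247	TD11	+	+	+	+	+	0	0
CRM2-CTG-389	TD12	+	+	+	+	+	0	0
CRM2-GAT-228	TD13	+	+	+	+	+	0	0
CRM2-GTC-188	TD14	+	+	+	+	+	0	0
CRM2-CGG-326	TD15	+	+	+	+	+	1	1
CRM2-AGC-GGC-257	TD16	+	+	+	+	+	0	0
CRM2-AGC-GGC-GAC-382	TD17	+	+	+	+	+	0	1
CRM2-CTT-256	TD18	+	+	+	+	+	1	0
CRM2-TAT-161	TD19	+	+	+	+	+	0	0
CRM2-TCC-345	TD20	+	+	+	+	+	0	0
CRM2-ACC-ATG-CTG-351	TD21	+	+	+	+	+	1	1
CRM2-AGA-138	TD22	+	+	+	+	+	0	0
CRM2-AGA-AGG-GGA-TCG-207	TD23	+	+	+	+	+	0	0
CRM2-ATC-TCA-220	TD24	+	+	+	+	+	0	0
CRM2-CAG-335	TD25	+	+	+	+	+	0	0
CRM2-CAT-AGT-227	TD26	+	+	+	+	+	0	0
CRM2-CGA-361	TD27	+	+	+	+	+	0	0
CRM2-CTC-199	TD28	+	+	+	+	+	0	0
CRM2-GCC-TTC-CCC-TAC-CCT-309	TD29	+	+	+	+	+	1	0
CRM2-GGG-186	TD30	+	+	+	+	+	0	0
CRM2-GGG-298	TD31	+	+	+	+	+	0	0
CRM2-TAC-140	TD32	+	+	+	+	+	0	0
CRM2-TAT-CAT-159	TD33	+	+	+	+	+	0	0
CRM2-TCC-350	TD34	+	+	+	+	+	0	0
CRM2-AAT-GAT-208	TD35	+	+	+	+	+	0	0
CRM2-AGC-CAG-CCG-275	TD36	+	+	+	+	+	0	0
CRM2-ATG-298	TD37	+	+	+	+	+	0	0
CRM2-GAC-AGC-AGT-CGT-ATT-AAT-185	TD38	+	+	+	+	+	0	0
CRM2-GTC-247	TD39	+	+	+	+	+	0	0
CRM2-AGG-328	TD40	+	+	+	+	+	0	1
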