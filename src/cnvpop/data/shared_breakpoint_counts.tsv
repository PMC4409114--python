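	YRI	CEU	AshkenaziJews	China_CHB	Tibet	India	JPT	Australia	NewWorld	Taiwan
YRI	-	127	229	184	73	83	92	85	73	157
CEU	127	-	257	190	42	86	72	99	64	194
AshkenaziJews	229	257	-	439	354	297	165	NA	333	NA
China_CHB	184	190	439	-	217	186	170	195	219	468
Tibet	73	42	354	217	-	263	62	67	NA	296
India	83	86	297	186	263	-	61	99	53	149
JPT	92	72	165	170	62	61	-	67	53	64
Australia	85	99	NA	195	67	99	67	-	118	284
NewWorld	73	64	333	219	NA	53	53	118	-	347
Taiwan	157	194	NA	468	296	149	64	284	347	-
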