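# Reference optimal parameters, thermal-explosion benchmark (example1), GA-ASA run.
alpha	b	c
-1.222686746438630	0.189242172392676	8.252947472264750
-2.523521838558800	0.932853654818075	-1.298732098734470
0.093712913166590	2.928861096270040	1.277936661162530
-3.184466684228680	0.032276934636307	7.151638887800430
0.841907376147177	0.624133706586784	6.016699202542360
0.543579681831342	2.609855976017300	4.653625396488530
2.180560092827050	-1.246422531808260	5.635726739884160
1.088558307376610	1.635782026957210	0.687577406535134
-1.174842130910290	-3.963774572717790	-5.326425392182380
1.017060692847850	-0.833587641581821	2.237065486971310
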