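# Reference optimal parameters, Neumann-left benchmark (example2, m=0.25), GA-ASA run.
alpha	b	c
0.464500439684582	-11.0028781120949	-12.7636935584212
-3.33324694261012	2.11315018577675	-5.37188638435383
-0.194337559721311	0.47470727444725	-0.042351193375573
-3.45408759766678	2.70099441007266	-3.75724365940641
-5.48801698503117	-14.9999432116995	-13.806030007752
-1.28645991543674	-2.97502002092667	2.6266679780155
-6.56302549714287	-5.15963787587387	-8.09010590696137
1.9884484940218	2.42668650849131	-5.97859767484604
-9.05563942802748	-1.15701411492891	-11.8680893657959
-1.05136593168004	-1.23760873949133	-10.0917104751297
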