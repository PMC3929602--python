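# Reference optimal parameters, Neumann-left benchmark (example2, m=0.25), GA-IPA run.
alpha	b	c
2.00000990197459	-2.53327380955379	-2.04436628299064
-1.28602583694444	0.628600926323132	-3.08615267144563
0.765196864102529	-0.826071194697222	-0.448002389749568
-3.36316154283773	1.94124108704907	-2.24922902674485
-2.81754759022593	1.90734595147276	-2.66329404646048
-0.749086831887256	-3.10918782644835	1.59601601647687
-2.56750443242766	-1.64680511116928	-2.3695938077251
1.67102584035366	3.3098175417873	-2.95032975955236
-2.91926666202298	-1.4378519528881	-1.43522291979122
-0.516212440164525	-0.623509775567634	-2.703478256228
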