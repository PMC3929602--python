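# Reference optimal parameters, Dirichlet-left benchmark (example3, m=0.75), GA-ASA run.
alpha	b	c
-2.73056565691944	3.49085467009396	-5.25776847865554
-4.33634711954231	0.23184895540015	4.31738960575493
3.80423016883327	1.80591217864829	4.67576012584760
0.01364375729467	9.41077798745202	1.15634974437215
0.80980144878077	-3.95901379093358	4.45931462422107
-2.33747274025478	5.28336935304114	6.13742438292330
1.88177593528183	2.61799608130219	-3.08482698001940
4.88126374826236	-4.73664684075954	-8.02792576795810
0.40997080411581	-1.47729741688129	2.21958697592547
0.33789053645730	-1.33529803313717	0.44393611859182
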