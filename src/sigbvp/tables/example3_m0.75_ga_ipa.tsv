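# Reference optimal parameters, Dirichlet-left benchmark (example3, m=0.75), GA-IPA run.
alpha	b	c
-2.83258569000288	2.98033056807418	-5.23172928318637
-4.42010332472099	0.13495932817614	4.02502515752573
3.30600805415091	2.08467745171526	4.03825862924909
0.00408821799800	8.27613404808222	1.33095013889441
1.32492260599249	-3.71698529742389	4.55970043938072
-2.30918802461094	4.73975316526285	6.29762522267394
1.71075781492918	2.37576486096926	-2.55486267649637
4.52199590675746	-4.38217408351950	-7.46847005821201
0.28578832784628	-1.39979371265597	2.03514844007566
0.55554404620260	-1.63197937784219	0.41337265836928
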