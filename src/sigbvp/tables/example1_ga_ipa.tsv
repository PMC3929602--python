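# Reference optimal parameters, thermal-explosion benchmark (example1), GA-IPA run.
alpha	b	c
-0.881133727216563	0.175902006189556	2.693904577232850
-1.914168112274790	1.024785387381440	-0.272756383809543
0.901876834716753	1.555229731984290	0.208750983272920
-1.947284050383540	0.246494504533957	2.816685127611610
0.319195846157371	0.311493860596170	2.589042884403360
0.338828303168466	1.412954189710230	2.134887086122020
1.815710626779760	-1.118954968300880	2.558280772425890
0.597896084699779	1.439765864844720	0.831615402493059
-0.910846359413137	-2.055541748351630	-2.280854618769590
0.921033436460622	-0.501229298596323	1.104201541521030
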