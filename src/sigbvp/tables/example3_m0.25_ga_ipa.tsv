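# Reference optimal parameters, Dirichlet-left benchmark (example3, m=0.25), GA-IPA run.
# KNOWN-DEFECTIVE TRANSCRIPTION: this block is corrupted in its source (the
# last bias duplicates the first verbatim) and does not reproduce the
# corresponding reference solution column; it is kept as transcribed for
# provenance.  See docs/methods.md.
alpha	b	c
-1.21283109847133	2.10611144213430	-1.74180188323508
1.03571174166241	3.33901417043102	1.97927968097166
2.54354943860472	-2.81356919290601	-1.82477617426169
-0.08380302331005	-0.89090920684382	-3.47294702330385
-3.78578617501133	2.34830432992743	-0.46468044922713
0.77113283421175	1.39103539510805	0.60221633923140
-0.39166723764742	-2.78667344812987	-2.71312485832199
2.60276365782489	3.24107191442605	2.25289685558876
-4.01442973095422	0.11578635663362	-1.55798487398090
-0.01034412572293	-0.73422658403828	-1.74180188323508
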