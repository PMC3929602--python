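# Reference optimal parameters, Dirichlet-left benchmark (example3, m=0.25), GA-ASA run.
alpha	b	c
-1.29954899127975	1.55618946670852	-4.97951286549580
0.36030995762761	4.54268965985819	-1.53639071233373
1.35509804608392	-3.67898087578096	1.22063364702299
-1.49517350846173	-8.31269717983695	-6.46006519243648
-3.56649523601647	2.84611416572567	-4.07363209952837
0.13571937537889	1.49401185018163	-1.64402410793090
-1.17448382336998	2.18102189143932	1.16234155281522
3.14946103860480	1.98119612209956	-0.89293215000584
-2.50385665347528	1.39658982973737	4.20709618704552
-0.21700379010878	-2.35736445901048	-5.76189602761190
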