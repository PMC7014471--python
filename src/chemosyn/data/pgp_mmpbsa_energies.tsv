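ligand	vdw	electrostatic	polar_solvation	sasa	mean_binding
alpha_caryophyllene	-133.59	23.59	49.38	-12.40	-73.01
beta_caryophyllene	-108.27	-0.22	32.02	-12.00	-88.46
beta_caryophyllene_oxide	-106.92	-2.60	39.94	-12.98	-82.57
verapamil	-212.66	-11.34	104.62	-23.58	-142.97
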