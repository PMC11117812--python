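variable	kind	ICM_mean	ICM_sd	ICM_percent	ICM_n	VCM_mean	VCM_sd	VCM_percent	VCM_n	printed_p
Age (years)	continuous	66.33	7.84		6	63.67	11.78		9	0.637
Sex (male)	categorical			100	6			88.89	9	0.699
LVEF (%)	continuous	38	15.87		6	48.13	10.88		9	0.164
LVEDD (mm)	continuous	60.33	2.16		6	60	5.15		9	0.885
LVESD (mm)	continuous	44	2.16		6	44.13	7.62		9	0.969
LA (mm)	continuous	47.50	2.65		6	52	5.61		9	0.092
High blood pressure	categorical			66.67	6			88.89	9	0.574
Dyslipidemia	categorical			66.67	6			55.56	9	0.975
Diabetes Mellitus	categorical			50	6			66.67	9	0.519
ACEI/ARAII	categorical			83.33	6			77.77	9	0.792
Diuretics	categorical			83.33	6			88.89	9	0.757
Calcium antagonist	categorical			16.67	6			22.22	9	0.792
Statins	categorical			83.33	6			77.78	9	0.792
Ezetrol	categorical			16.67	6			22.22	9	0.792
Metformin	categorical			33.33	6			33.33	9	>0.999
Metformin/IGP4	categorical			16.67	6			22.22	9	0.792
Insulin	categorical			16.67	6			22.22	9	0.792
Aspirin	categorical			100	6			22.22	9	0.003
Beta-blocker	categorical			83.33	6			77.78	9	0.792
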