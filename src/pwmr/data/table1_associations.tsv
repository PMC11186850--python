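exposure	outcome	chrom	n_outcomes	tier	or_estimate	ci_low	ci_high	pval	p_het	p_ple	p_heidi	pp_h4	sensitivity_pass	confirmation_status
PNKP	Any migraine	19	1	2	1.312	1.169	1.472	4.05e-6	<0.01	0.03	0.09	0.99	yes	confirmed
CALCB	Any migraine	11	1	2	0.907	0.869	0.947	9.80e-6	0.04	0.28	<0.01	0.98	yes	confirmed
FER	Any migraine	5	2	3	1.138	1.075	1.205	9.35e-6	0.04	0.01	0.01	0.96	no	confirmed
ITIH4	Any migraine	3	3	1	0.862	0.802	0.926	4.69e-5	0.39	0.51	0.06	0.92	yes	confirmed
LRP11	Any migraine	6	4	1	0.968	0.955	0.981	1.27e-6	0.62	0.24	0.10	0.89	yes	confirmed
SERPING1	Any migraine	11	2	3	0.959	0.942	0.976	3.49e-6	<0.01	0.18	<0.01	0.89	no	confirmed
ITIH1	Any migraine	3	2	1	1.044	1.024	1.065	1.08e-5	0.78	0.85	0.65	0.87	yes	confirmed
ADGRF5	Any migraine	6	2	1	0.964	0.946	0.982	8.74e-5	0.80	0.88	0.74	0.84	yes	confirmed
PLG	Any migraine	6	3	3	1.050	1.024	1.076	1.59e-4	0.47	0.50	0.30	0.30	no	confirmed
INHBC	BRH	12	1	2	1.507	1.282	1.770	6.08e-7	0.23	0.95	0.01	0.98	yes	confirmed
PLCG1	BRH	20	3	3	1.221	1.105	1.349	9.30e-5	0.00	NA	0.18	0.62	no	confirmed
LRP11	BRH	6	4	2	0.969	0.954	0.984	9.36e-5	0.91	0.82	0.37	0.62	yes	confirmed
SERPING1	BRH	11	2	3	0.952	0.929	0.975	4.93e-5	0.09	0.99	0.04	0.47	no	confirmed
MRVI1	MO	11	3	2	0.800	0.714	0.896	1.13e-4	0.03	0.63	0.02	0.99	yes	confirmed
CHST4	MO	16	1	2	1.373	1.190	1.586	1.52e-5	0.01	NA	0.06	0.87	yes	confirmed
GP1BA	VD	17	1	2	0.811	0.730	0.900	8.54e-5	0.49	0.93	0.77	0.94	yes	confirmed
ITIH1	VD	3	2	1	1.067	1.031	1.103	1.61e-4	0.23	0.18	0.73	0.89	yes	confirmed
LRP11	VD	6	4	1	0.958	0.936	0.980	2.14e-4	0.41	0.62	0.11	0.83	yes	confirmed
SPINK7	VD	5	2	2	0.864	0.800	0.933	1.89e-4	<0.01	0.40	0.01	0.74	yes	confirmed
LGALS4	VD	19	3	2	0.859	0.795	0.929	1.33e-4	0.22	0.32	0.58	0.70	yes	confirmed
ARHGAP25	VD	2	1	3	0.879	0.822	0.939	1.42e-4	0.79	0.50	0.11	0.34	yes	failed
ISOC1	VD	5	3	3	0.907	0.862	0.954	1.57e-4	0.67	0.59	0.77	0.06	yes	confirmed
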