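patient_id	sex	age	implant_type	n_implanted	n_stimulated	left_structures	right_structures	mtr_left_implanted	mtr_left_stimulated	mtr_right_implanted	mtr_right_stimulated	group
P1	M	62	S-EEG	106	28	amygdala,hippocampus	amygdala,hippocampus	7	4	7	5	multifocal_mtr
P2	M	26	Grid+strip+S-EEG	136	24	amygdala,hippocampus,entorhinal	amygdala,hippocampus,entorhinal,parahippocampal	14	6	26	6	multifocal_mtr
P3	F	26	S-EEG	134	44	amygdala,entorhinal,parahippocampal	amygdala,parahippocampal	9	4	9	8	multifocal_mtr
P4	F	24	S-EEG	140	37	amygdala,hippocampus	none	13	10	0	0	non_epileptogenic_mtr
P5	F	39	S-EEG	92	47	amygdala,hippocampus	hippocampus	7	5	9	6	multifocal_mtr
P6	F	26	S-EEG	98	38	amygdala,hippocampus	none	13	4	0	0	non_epileptogenic_mtr
P7	F	42	Grid+S-EEG	214	18	amygdala,hippocampus,entorhinal,parahippocampal	amygdala,hippocampus,entorhinal,parahippocampal	22	6	0	0	multifocal_mtr
P8	M	48	S-EEG	103	34	hippocampus	hippocampus	5	4	7	4	multifocal_mtr
P9	F	23	S-EEG	108	35	amygdala,hippocampus	amygdala,hippocampus	11	10	7	4	focal_mtr
P10	F	23	S-EEG	176	53	amygdala,hippocampus,entorhinal	amygdala,hippocampus,entorhinal,parahippocampal	10	4	14	6	non_epileptogenic_mtr
P11	M	51	S-EEG	114	20	amygdala,hippocampus,parahippocampal	amygdala,hippocampus,parahippocampal	10	0	11	10	multifocal_mtr
P12	M	32	S-EEG	92	26	amygdala	amygdala,hippocampus	5	0	9	4	multifocal_mtr
P13	M	19	S-EEG	84	36	amygdala,hippocampus,entorhinal,parahippocampal	none	19	8	0	0	focal_mtr
P14	F	35	S-EEG	84	46	amygdala,hippocampus,entorhinal,parahippocampal	amygdala,hippocampus,parahippocampal	10	6	16	12	focal_mtr
P15	M	57	S-EEG	70	28	amygdala,hippocampus,parahippocampal	amygdala,hippocampus	7	4	6	0	focal_mtr
P16	M	40	S-EEG	72	35	amygdala,hippocampus,entorhinal,parahippocampal	none	13	4	0	0	non_epileptogenic_mtr
P17	F	32	S-EEG	74	44	amygdala,hippocampus	amygdala,hippocampus	6	6	5	2	non_epileptogenic_mtr
P18	F	53	S-EEG	66	52	amygdala,hippocampus	amygdala,hippocampus	9	8	7	6	multifocal_mtr
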