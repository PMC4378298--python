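participant	age_years	sex	post_stroke_months	mmse	lesion_note
1	55	F	5	30	L thal. hem.
2	55	M	1	27	L basal ganglia
3	52	M	8	24	R cingulate gyrus infarct
4	74	F	9	30	R caudate infarct
5	65	F	7	28	L caudate infarct
6	54	M	11	27	R putamen hem.
7	50	M	5	30	R lacunar infarct (Globus pallidus)
8	69	F	8	28	R motor cortex infarct
9	64	M	54	28	R basal ganglia, thalamic hem.
10	42	M	5	30	R pontine infarct
11	55	M	7	28	L internal capsule
12	62	M	7	28	L thalamic hem.
13	73	M	5	28	L pontomedullary
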