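pt	a	n_drug	ror	ci_low	ci_high	prr	chi2
failure of child-resistant product closure		70792	182.16	121.30	273.54		4094.09
nsaid-exacerbated respiratory disease		70792	161.43	124.14	209.93		8783.94
aspirin-exacerbated respiratory disease		70792	68.50	56.27	83.38		6552.15
bronchopulmonary dysplasia		70792	56.16	46.01	68.55		5193.93
glomerulonephritis minimal lesion		70792	43.44	34.70	54.38		3121.73
renal tubular acidosis		70792	34.57	29.80	40.10		5647.44
drug effective for unapproved indication	2459	70792	26.63	25.52	27.80		51425.10
lip oedema		70792	26.11	23.09	29.53		6096.84
poor-quality drug administered		70792	20.82	18.75	23.12		6582.94
meningitis aseptic		70792	18.97	16.46	21.85		3248.81
duodenal ulcer		70792	17.55	15.65	19.69		4529.49
product administered to patient of inappropriate age		70792	16.74	14.90	18.80		4203.42
accidental exposure to product by child		70792	14.85	13.38	16.48		4546.16
gastric ulcer		70792	12.59	11.62	13.64		6357.27
upper gastrointestinal haemorrhage		70792	11.70	10.72	12.78		4854.22
angioedema	1636	70792	11.54	10.97	12.13	11.29	14491.17
toxic epidermal necrolysis		70792	10.40	9.47	11.44		3639.32
melaena		70792	10.37	9.57	11.23		5029.26
oral discomfort		70792	10.27	9.29	11.35		3185.19
gastric haemorrhage		70792	10.20	9.21	11.29		3066.28
haematemesis		70792	9.95	9.21	10.75		5193.09
tubulointerstitial nephritis		70792	9.43	8.66	10.26		4011.49
metabolic acidosis		70792	7.55	7.01	8.13		4008.25
intentional overdose	1664	70792	7.50	7.14	7.88		8798.20
anaphylactic reaction	1052	70792	6.64	6.24	7.06		4785.54
suicide attempt	1070	70792	4.95	4.66	5.26		3231.44
drug hypersensitivity	3407	70792	4.85	4.69	5.03	4.67	9675.03
product use in unapproved indication	3569	70792	4.83	4.67	5.00		10036.44
acute kidney injury	1782	70792	3.93	3.75	4.12	3.86	3713.88
urticaria	1828	70792	3.88	3.70	4.06	3.80	3722.68
abdominal pain upper	1638	70792	2.82	2.68	2.96	2.78	1850.02
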