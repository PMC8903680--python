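shift_ppm	metabolite	tolerance_ppm
0.89006	Cholesterol	0.01
0.92847	Isoleucine	0.01
0.95118	Unknown	0.01
0.95702	Leucine	0.01
0.99919	Isoleucine	0.01
1.26482	Lipids (CH2)	0.01
1.40660	Unknown	0.01
1.90859	Acetate	0.01
2.22215	Lipids (CH2CH=CH)	0.01
2.36196	Pyruvic acid	0.01
2.63742	Methionine	0.01
2.91618	Dimethylglycine	0.01
3.35396	Unknown	0.01
3.58832	1,5-Anhydrosorbitol	0.01
3.59782	Valine	0.01
3.62232	Myoinositol	0.01
3.72103	Glucose	0.01
3.92001	Creatine	0.01
3.95567	Serine	0.01
4.04386	Creatinine	0.01
4.12106	Proline	0.01
4.50117	Unknown	0.01
5.22921	Glucose	0.01
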