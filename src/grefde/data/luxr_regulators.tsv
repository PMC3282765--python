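gene_id	length_aa	atp_motif	hth	lal
SCO0132	919	1	1	1
SCO0712	941	0	1	0
SCO0877	888	1	1	1
SCO1331	780	1	1	1
SCO1351	912	1	1	1
SCO2686	338	0	1	0
SCO3665	327	0	1	0
SCO3666	394	0	1	0
SCO4263	1251	0	1	0
SCO4276	223	0	1	0
SCO4768	203	0	1	0
SCO5065	943	1	1	1
SCO5506	1091	1	1	1
SCO6029	220	0	1	0
SCO6193	943	1	1	1
SCO6334	892	1	1	1
SCO6993	606	1	1	0
SCO7093	932	1	1	1
SCO7134	923	1	1	1
SCO7137	924	1	1	1
SCO7143	937	1	1	1
SCO7173	908	1	1	1
SCO7295	988	1	1	1
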