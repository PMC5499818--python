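species	total_trnas	n_concordant	concordance_percent	n_fav_lacking	n_lacking
H. sapiens	589	9	50.0	2	6
C. elegans	563	12	66.7	6	15
M. musculus	441	12	66.7	2	8
R. norvegicus	385	10	55.6	5	13
D. melanogaster	268	12	66.7	6	18
S. cerevisiae	259	15	83.3	3	20
S. pombe	158	15	83.3	2	16
C. albicans	119	15	83.3	3	20
H. capsulatum	71	8	44.4	5	16
P. falciparum	33	14	77.8	7	26
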