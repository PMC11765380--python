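species	group	pcg	nps1_total	per_pcg1_printed	nps2_total	per_pcg2_printed	nps3_total	per_pcg3_printed
Escherichia coli	Bacteria	6066	7238	1.2	7368	1.2	37528	6.2
Staphylococcus aureus	Bacteria	10245	11254	1.1	11254	1.1	59712	5.8
Podospora anserina	Fungi	100	102	1	102	1	202	2
Saccharomyces cerevisiae	Fungi	6727	14794	2.2	16572	2.5	100972	15
Schizosaccharomyces pombe	Fungi	5201	7934	1.5	8188	1.6	37196	7.2
Apis mellifera	Animal	99	172	1.7	193	1.9	842	8.5
Caenorhabditis elegans	Animal	4484	7914	1.8	22490	5	69332	15.5
Callithrix jacchus	Animal	110	494	4.5	625	5.7	2072	18.8
Canis lupus familiaris	Animal	848	3510	4.1	4276	5	12307	14.5
Cavia porcellus	Animal	306	931	3	1185	3.9	3272	10.7
Chlorocebus aethiops	Animal	128	558	4.4	709	5.5	2578	20.1
Danio rerio	Animal	3338	4483	1.3	7067	2.1	32953	9.9
Drosophila melanogaster	Animal	3796	12844	3.4	35464	9.3	151871	40
Equus caballus	Animal	292	1159	4	1302	4.5	5962	20.4
Gallus gallus	Animal	2309	4229	1.8	7058	3.1	33259	14.4
Heterocephalus glaber	Animal	6	13	2.2	13	2.2	13	2.2
Macaca mulatta	Animal	365	1374	3.8	1851	5.1	9108	25
Homo sapiens	Animal	20429	228613	11.2	722907	35.4	3245524	158.9
Mus musculus	Animal	17775	82775	4.7	202478	11.4	749909	42.2
Oryctolagus cuniculus	Animal	978	4381	4.5	5598	5.7	19569	20
Ovis aries	Animal	467	1620	3.5	1927	4.1	8340	17.9
Rattus norvegicus	Animal	8202	38059	4.6	60773	7.4	217124	26.5
Sus scrofa	Animal	1459	6486	4.4	7600	5.2	27664	19
Xenopus laevis	Animal	3507	4814	1.4	6734	1.9	47145	13.4
Arabidopsis thaliana	Plant	16431	29015	1.8	76736	4.7	395227	24.1
Oryza sativa	Plant	4190	5256	1.3	7902	1.9	28387	6.8
Panax ginseng	Plant	135	150	1.1	159	1.2	159	1.2
Pinus koraiensis	Plant	71	82	1.2	82	1.2	82	1.2
Triticum aestivum	Plant	381	505	1.3	505	1.3	3267	8.6
Zea mays	Plant	853	1152	1.4	1560	1.8	12859	15.1
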