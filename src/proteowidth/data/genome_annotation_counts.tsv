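species	taxon_id	genes_ensembl	pcg_swissprot	percent_printed	group
Staphylococcus aureus	1280	6220	10245	164	Bacteria
Escherichia coli	83333	5079	6066	119	Bacteria
Homo sapiens	9606	19846	20429	103	Animal
Saccharomyces cerevisiae	559292	6600	6727	101	Fungi
Schizosaccharomyces pombe	284812	5145	5201	101	Fungi
Pinus koraiensis	88728	71	71	100	Plant
Mus musculus	10090	21700	17228	82	Animal
Arabidopsis thaliana	3702	27655	16389	59	Plant
Rattus norvegicus	10116	24964	8205	32	Animal
Drosophila melanogaster	7227	13986	3796	27	Animal
Caenorhabditis elegans	6239	19985	4487	22	Animal
Gallus gallus	9031	17077	2309	13	Animal
Oryza sativa	39947	35804	4190	11	Plant
Danio rerio	7955	30153	3343	11	Animal
Sus scrofa	9823	22040	1459	6.6	Animal
Oryctolagus cuniculus	9986	20599	978	4.7	Animal
Canis lupus familiaris	9615	20974	854	4	Animal
Xenopus laevis	8355	108155	3507	3.2	Animal
Panax ginseng	4054	6050	135	2.2	Plant
Zea mays	4577	39756	853	2.1	Plant
Ovis aries	9940	21890	467	2.1	Animal
Cavia porcellus	10141	18095	306	1.6	Animal
Macaca mulatta	9544	21591	365	1.6	Animal
Equus caballus	9796	21426	292	1.3	Animal
Apis mellifera	7460	9935	99	1	Animal
Podospora anserina	515849	10544	100	0.9	Fungi
Chlorocebus aethiops	9534	19165	128	0.6	Animal
Callithrix jacchus	9483	21965	110	0.5	Animal
Triticum aestivum	4565	145065	381	0.2	Plant
Heterocephalus glaber	10181	23320	6	0.03	Animal
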