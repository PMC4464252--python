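length	mapped	intergenic	genic	promoter	gene_body	intron	exon
20	114233	41928	72305	35197	37108	11712	25396
21	553289	205532	347757	172777	174980	52227	122753
22	253020	88252	164768	73132	91636	27515	64121
23	537380	232440	304940	195293	109647	49544	60103
24	4387009	2001459	2385550	1539302	846248	387823	458425
25	220819	90824	129995	77841	52154	20234	31920
26	18290	3972	14318	3062	11256	1868	9388
27	8895	1196	7699	743	6956	966	5990
28	4356	553	3803	291	3512	531	2981
29	1465	193	1272	80	1192	163	1029
30	413	61	352	31	321	46	275
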