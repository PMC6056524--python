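arm_id	chrom	start	end
1p	1	0	121535434
1q	1	124535434	249250621
2p	2	0	92326171
2q	2	95326171	243199373
3p	3	0	90504854
3q	3	93504854	198022430
4p	4	0	49660117
4q	4	52660117	191154276
5p	5	0	46405641
5q	5	49405641	180915260
6p	6	0	58830166
6q	6	61830166	171115067
7p	7	0	58054331
7q	7	61054331	159138663
8p	8	0	43838887
8q	8	46838887	146364022
9p	9	0	47367679
9q	9	50367679	141213431
10p	10	0	39254935
10q	10	42254935	135534747
11p	11	0	51644205
11q	11	54644205	135006516
12p	12	0	34856694
12q	12	37856694	133851895
13p	13	0	16000000
13q	13	19000000	115169878
14p	14	0	16000000
14q	14	19000000	107349540
15p	15	0	17000000
15q	15	20000000	102531392
16p	16	0	35335801
16q	16	38335801	90354753
17p	17	0	22263006
17q	17	25263006	81195210
18p	18	0	15460898
18q	18	18460898	78077248
19p	19	0	24681782
19q	19	27681782	59128983
20p	20	0	26369569
20q	20	29369569	63025520
21p	21	0	11288129
21q	21	14288129	48129895
22p	22	0	13000000
22q	22	16000000	51304566
Xp	X	0	58632012
Xq	X	61632012	155270560
Yp	Y	0	10104553
Yq	Y	13104553	59373566
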