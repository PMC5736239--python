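#chrom	length	cen_start	cen_end
1	247249719	121236957	123476957
2	242951149	91689898	94689898
3	199501827	90587544	93487544
4	191273063	49354874	52354874
5	180857866	46441398	49441398
6	170899992	58938125	61938125
7	158821424	58058273	61058273
8	146274826	43958052	46958052
9	140273252	46367679	50203279
10	135374737	39244941	41624941
11	134452384	51450781	54450781
12	132349534	34747961	36142961
13	114142980	16000000	17868000
14	106368585	15070000	18070000
15	100338915	15260000	18260000
16	88827254	35143302	36943302
17	78774742	22187133	22287133
18	76117153	15400898	16764896
19	63811651	26923622	29923622
20	62435964	26267569	28033230
21	46944323	10260000	13260000
22	49691432	11330000	14330000
X	154913754	58598737	61632012
Y	57772954	11253954	12308578
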