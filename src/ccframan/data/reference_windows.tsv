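window_id	low_cm1	high_cm1	representative_cm1	assignment	Healthy Male ccfDNA	Healthy Female ccfDNA	MCF12A ccfDNA	MCF12A gDNA	MCF7 ccfDNA	MCF7 gDNA	Adj BRCA	Meta BRCA	Neoadj BRCA	T2DM Male ccfDNA	Prediabetic Male ccfDNA	Seq BRCA
(1)	522	536	529	524 S-S disulfide stretch (proteins, phosphatidylserine); 529 uracil (weak); 536 adenine	1	1	1	1	1	1	1	1	1	1	1	1
(2)	621	624	623	623 ring breathing of adenine	0	0	1	1	0	0	0	0	0	0	0	0
(3)	725	725	725	726 15N-adenine	0	0	0	0	0	0	0	0	1	0	0	0
(4)	740	769	746	746 ring breathing mode of thymine	1	1	1	1	1	1	1	1	1	1	1	1
(5)	780	789	780	780 DNA, thymine, cytosine	0	0	0	0	1	1	0	0	0	0	0	0
(6)	879	889	883	883 five-ring deformation, single-adenine oligonucleotide	1	1	1	1	1	1	0	0	0	1	1	0
(7)	912	917	914.5	915 ribose vibration (distinct RNA mode); 913 deoxyribose	0	1	0	0	1	1	0	0	0	0	0	1
(8)	963	963	963	963 NH2 rocking of thiolated adenine mononucleotide	1	0	0	0	0	0	0	0	0	1	0	0
(9)	1002	1009	1002	1002 CH3 rocking in methylated cytosine; adenine, cytosine	1	1	1	1	1	1	1	1	1	1	1	1
(10)	1042	1068	1050	1050 PO2- symmetric stretch	1	1	1	1	1	1	0	0	0	0	0	0
(11)	1101	1101	1101	1101 O-P-O backbone stretch	0	0	0	0	0	0	0	0	0	0	0	1
(12)	1130	1138	1134	1134 adenine	0	0	1	1	0	0	0	0	0	0	0	0
(13)	1223	1246	1223	1223 cellular nucleic acids	0	0	1	1	1	1	0	0	0	0	0	1
(14)	1302	1302	1302	1302 5-methyl substituted cytidine	0	0	0	0	0	0	0	0	1	0	0	0
(15)	1336	1336	1336	1336 purine bases (guanine)	0	0	0	0	0	0	0	0	1	0	0	0
(16)	1345	1348	1346	1346 C-N stretch of pyrimidine of thymine	1	1	0	0	0	0	0	0	0	0	0	0
(17)	1372	1372	1372	1373 thymine, adenine, guanine ring breathing	0	0	0	0	0	0	0	0	0	0	0	1
(18)	1399	1399	1399	1398 C-O symmetric stretch	0	0	0	0	0	0	0	0	0	0	0	1
(19)	1451	1469	1460	1462 poly-A; 1463 N1-H / C4-C5 (cytosine), CH	1	1	1	1	1	1	1	1	1	1	1	1
(20)	1545	1555	1545	1545 C6-H deformation	0	0	1	1	1	1	0	0	0	0	0	1
(21)	1574	1578	1576	1577 purine bands, mainly G + A (increase upon methylation); 1580 G, A	0	0	1	1	0	0	0	0	1	0	0	0
(22)	1603	1603	1603	1603 cytosine NH2	0	0	0	0	0	0	1	1	0	0	0	1
(23)	1643	1655	1655	1655 T, G, C ring breathing (DNA/RNA bases)	0	0	0	0	1	1	0	0	0	0	0	0
(24)	2883	2891	2889	2889 CH2 asymmetric stretch of lipids and proteins	1	1	1	1	1	1	1	1	1	1	1	1
(25)	2918	2950	2940	2940 CH2 asymmetric stretch	1	1	1	1	1	1	1	1	1	1	1	1
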