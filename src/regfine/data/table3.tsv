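snp	gene	function	position	score_3d	regdb	w3d	wregdb	eqtl	enhancer	rsnp	pchic	tfbs	asb	total	bold
rs8043085	RASGRP1	intron 2	38828140	25.72	5	2	2	1	1	1	1	1	0	9	0
rs8032939	RASGRP1	intron2	38834033	4.67	7	0	0	3	1	1	1	1	1	8	0
rs8035957	RASGRP1	intron2	38838264	1.85	7	0	0	4	1	1	0	1	1	8	0
rs28536554	RASGRP1	intron2	38838432	2.12	6	0	1	2	1	1	0	1	1	7	0
rs72727387	RASGRP1	intron2	38843476	3.55	6	0	1	2	2	1	0	1	1	8	0
rs72727388	RASGRP1	intron2	38843694	3.56	7	0	0	2	2	1	0	1	1	7	0
rs28582094	RASGRP1	intron2	38843887	4.04	6	0	1	2	2	1	0	1	1	8	0
rs12593201	RASGRP1	intron2	38844106	5.49	7	0	0	3	2	1	1	1	1	9	0
rs36027443	RASGRP1	intron2	38846347	11.23	5	1	2	2	2	0	1	1	0	9	0
rs7170151	RASGRP1	intron2	38846678	20.04	3a	2	4	3	2	1	1	1	1	15	1
rs6495979	RASGRP1	intron2	38847359	8.79	7	1	0	3	2	1	1	1	1	10	1
rs11348849	RASGRP1	intron2	38847877	8.09	7	1	0	0	2	1	1	0	0	5	0
rs11631591	RASGRP1	intron2	38850262	6.86	3a	1	4	2	2	1	1	1	1	13	1
rs7173565	RASGRP1	intron2	38850330	8.41	4	1	3	4	2	1	1	1	1	14	1
rs62006173	RASGRP1-C15orf53	intergenic	38906396	2.36	6	0	1	0	0	0	0	1	3	5	0
rs11073341	RASGRP1-C15orf53	intergenic	38908135	1.26	5	0	2	3	0	0	0	1	3	9	0
rs9920715	RASGRP1-C15orf53	intergenic	38916906	7.83	3a	1	4	3	0	0	1	1	2	12	1
rs12900339	RASGRP1-C15orf53	intergenic	38927386	0.81	6	0	1	3	0	0	0	1	3	8	0
rs12324579	RASGRP1-C15orf110	intergenic	38927510	1	7	0	0	1	0	0	0	0	0	1	0
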