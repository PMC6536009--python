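snp	gene	function	position	a1	a2	p_3as	p_ch	p_eu	p_jap	p_meta	or_meta	ci_low	ci_high	het_p	direction
rs8043085	RASGRP1	intron 2	38828140	T	G	3.91E-03	5.53E-01	1.02E-03	4.52E-05	2.68E-08	1.11	1.1	1.16	0.3072	++++++
rs8032939	RASGRP1	intron 2	38834033	T	C	1.40E-04	5.81E-02	1.03E-03	4.35E-05	3.16E-11	0.88	0.85	0.92	0.4913	------
rs8035957	RASGRP1	intron 2	38838264	T	C	2.52E-04	4.89E-02	1.40E-03	5.14E-05	1.31E-10	0.89	0.85	0.92	0.5035	------
rs28536554	RASGRP1	intron 2	38838432	T	A	6.37E-03	3.13E-01	9.72E-04	1.72E-05	1.15E-08	0.89	0.9	0.93	0.3438	------
rs72727387	RASGRP1	intron 2	38843476	A	G	3.43E-03	2.71E-01	3.65E-03	3.92E-05	2.54E-08	1.11	1.07	1.15	0.4756	++++++
rs72727388	RASGRP1	intron 2	38843694	C	T	3.36E-03	2.70E-01	3.67E-03	3.92E-05	2.55E-08	0.90	0.9	0.93	0.4756	------
rs28582094	RASGRP1	intron 2	38843887	G	A	3.77E-03	2.62E-01	2.34E-03	4.16E-05	1.87E-08	0.90	0.87	0.93	0.4971	------
rs12593201	RASGRP1	intron 2	38844106	A	G	3.25E-03	2.62E-01	2.91E-03	3.92E-05	1.90E-08	1.11	1.1	1.15	0.4893	++++++
rs36027443	RASGRP1	intron 2	38846347	A	G	3.79E-03	2.78E-01	2.69E-03	3.63E-05	3.08E-08	1.11	1.07	1.15	0.4629	++++++
rs7170151	RASGRP1	intron 2	38846678	C	T	3.36E-04	5.28E-02	2.72E-03	5.93E-05	2.69E-10	1.13	1.1	1.17	0.4429	++++++
rs6495979	RASGRP1	intron 2	38847359	C	T	3.21E-04	6.55E-02	3.02E-03	7.01E-05	3.18E-10	1.13	1.09	1.17	0.3495	++++++
rs11348849	RASGRP1	intron 2	38847877	I	D	3.30E-04	6.84E-02	3.71E-03	6.20E-05	3.62E-10	1.13	1.07	1.22	0.3029	++++++
rs11631591	RASGRP1	intron 2	38850262	T	C	2.53E-04	7.00E-02	3.49E-03	6.51E-05	3.43E-10	0.89	0.9	0.92	0.2393	------
rs7173565	RASGRP1	intron 2	38850330	T	C	2.83E-04	7.01E-02	3.50E-03	6.51E-05	3.79E-10	0.89	0.9	0.92	0.2677	------
rs62006173	RASGRP1-C15orf101	intergenic	38906396	T	C	2.06E-04	1.04E-02	1.54E-01	1.94E-03	4.50E-08	0.87	0.8	0.92	0.6036	------
rs11073341	RASGRP1-C15orf102	intergenic	38908135	G	A	1.38E-04	9.76E-04	1.28E-01	8.25E-04	3.67E-08	1.11	1.1	1.16	0.04208	++++++
rs9920715	RASGRP1-C15orf103	intergenic	38916906	T	C	4.21E-05	1.10E-03	5.90E-02	1.34E-03	5.11E-09	0.89	0.86	0.93	0.06495	------
rs12900339	RASGRP1-C15orf109	intergenic	38927386	G	A	2.75E-06	3.39E-01	3.28E-01	2.69E-04	9.19E-07	1.09	1.1	1.14	0.0166	++++++
rs12324579	RASGRP1-C15orf110	intergenic	38927510	C	G	1.20E-05	8.56E-02	3.00E-01	1.09E-05	1.80E-08	0.90	0.9	0.93	0.02404	------
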