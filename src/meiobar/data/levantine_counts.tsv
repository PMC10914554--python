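station	Nematoda	Copepoda	Polychaeta	Isopoda	Ostracoda	Cumacea	Mollusca
HS54	7168	1314	482	43	26	2	2
HS122	3548	544	166	21	5	8	2
HS394	13744	473	174	4	2	2	10
HS771	5452	133	169	22		1	5
HS1134	716	30	40
HS1418	46		3
TA76	9060	1168	282	68	11
TA154	4949	774	129	14	4	8
TA401	3113	129	134	4
TA941	868	295	34		1
TA1173	403	118	14			1
TA1400	241	51	1
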