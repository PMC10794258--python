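nest_id	year	laying_date	emergence_date	beach	n_samples	haplotype	haplotype_origin	pct_polymorphic	mean_ho	sd_ho	mean_relatedness
SP01	2016	2016-07-03	2016-09-05	Les Palmeres (Sueca)	2	CC-A2.1	Shared	43.39	0.255	0.01	0.082
SP02	2017	NA	2017-10-11	Migjorn (Peniscola)	2	CC-A1.1	Atlantic	38.19	0.253	0.006	0.180
SP03	2018	2018-06-15	2018-08-08	Sant Simo (Mataro)	NA	NA	NA	NA	NA	NA	NA
SP04	2018	2018-08-01	2018-09-28	La Descarrega (Premia de Mar)	8	CC-A3.1	Shared	48.8	0.253	0.008	0.235
SP05	2018	NA	2018-09-16	Vilafortuny (Cambrils)	4	CC-A2.1	Shared	43.3	0.275	0.035	0.301
SP06	2018	NA	2018-09-24	Ardiaca (Cambrils)	NA	NA	NA	NA	NA	NA	NA
SP07	2019	2019-07-13	2019-09-14	Del Serradal (Castellon de la Plana)	7	CC-A31.1	Mediterranean	49.24	0.279	0.046	0.229
SP08	2019	2019-07-25	2019-09-10	D'en Bossa (Sant Jordi de ses Salines)	7	CC-A2.1	Shared	52.68	0.317	0.051	0.221
SP09	2019	2019-07-28	2019-09-18	Calblanque (Cartagena)	7	CC-A2.1	Shared	50.72	0.283	0.045	0.216
SP10	2019	2019-07-29	NA	D'es Cavallet (Sant Francesc de s'Estany)	NA	NA	NA	NA	NA	NA	NA
SP11	2019	NA	2019-10-06	Castelldefels (Castelldefels)	8	CC-A31.1	Mediterranean	47.4	0.243	0.006	0.225
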