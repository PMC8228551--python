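study_id	country	brain_regions	sample_size_pd	age_at_death_years	disease_duration_years	postmortem_interval_hours	braak_stage	n_mirnas_reported	n_up	n_down
kim2007	USA	midbrain;cerebellum;frontal cortex;prefrontal cortex	3	70	NA	NA	NA	1	0	1
sethi2009	USA	temporal cortex	4	69	NA	1.2	NA	0	0	0
minones-moyano2011	Spain	substantia nigra;amygdala;cerebellum;frontal cortex	14	72	NA	6.4	4	2	0	2
cho2013	USA	frontal cortex	15	80	NA	8.2	3.5	1	0	1
alvarez-erviti2013	Spain	substantia nigra;amygdala	6	76	NA	4.8	NA	6	6	0
kim2014	USA	substantia nigra	8	78	NA	20.7	NA	1	1	0
schlaudraff2014	Germany	substantia nigra	5	78	NA	16	NA	0	0	0
villar-menendez2014	Spain	putamen	6	76	NA	7.9	4	1	0	1
cardo2014	UK	substantia nigra	8	77	4,25	45.8	NA	10	9	1
briggs2015	USA	substantia nigra	8	NA	NA	NA	NA	17	15	2
pantano2015	Spain	amygdala	7	70	NA	NA	NA	0	0	0
wake2016	USA	prefrontal cortex	29	77	NA	8	NA	0	0	0
tatura2016	Germany	anterior cingulate cortex	22	73	NA	30.6	NA	5	5	0
nair2016	USA	putamen	12	75	NA	13.4	NA	13	6	7
hoss2016	USA	prefrontal cortex	29	77	10,5	11.1	NA	29	11	18
chatterjee2017	India	prefrontal cortex	29	NA	NA	NA	NA	11	9	2
mcmillan2017	UK	substantia nigra	6	83	16,1	NA	NA	1	0	1
xing2020	China	prefrontal cortex	15	70	5,5	NA	NA	3	0	3
hu2020	China	substantia nigra	4	NA	NA	NA	NA	1	0	1
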