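disease	protein	discovery_fdr	discovery_ci_lo	discovery_ci_hi	replication_pval	replication_ci_lo	replication_ci_hi	q_pval	intercept_pval	pph4
DR	WARS	1.31E-04	0.095	0.208	3.01E-07	0.21	0.45	4.42E-01	4.80E-01	94.4%
DR	HSPA1A	4.96E-04	-1.067	-0.46	8.89E-01	NA	NA	1.45E-147	NA	0.0%
DR	KLK8	1.10E-02	0.105	0.288	5.78E-01	NA	NA	1.45E-147	4.91E-02	78.3%
DR	SIRPG	1.46E-02	0.071	0.201	3.32E-04	0.18	0.62	NA	NA	80.7%
DR	KLK11	4.35E-02	0.222	0.696	4.94E-01	NA	NA	1.30E-01	6.01E-01	1.0%
PDR	OLFML3	3.75E-03	0.238	0.591	2.19E-02	0.09	1.12	1.08E-01	NA	0.0%
PDR	ALDOC	5.48E-03	0.246	0.637	9.28E-06	0.34	0.87	NA	NA	99.2%
PDR	SIRPG	4.73E-02	0.068	0.208	6.65E-05	0.23	0.68	NA	NA	93.4%
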