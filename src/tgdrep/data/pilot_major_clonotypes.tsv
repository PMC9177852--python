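patient_id	disease	course	tgd_fraction_pbmc	chain	v_call	d_call	j_call	frequency_pct	cdr3_aa
pt1	HSTCL	not_applicable	0.87	TRG	TRGV8		TRGJ1/2	97.38	CATWDSSYYKKLF
pt1	HSTCL	not_applicable	0.87	TRD	TRDV1	TRDD3	TRDJ1	99.52	CALALPGIRGYTDKLIF
pt2	HSTCL	not_applicable	0.95	TRG	TRGV3		TRGJ1/2	98.20	CATWDRLHYYKKLF
pt2	HSTCL	not_applicable	0.95	TRD	TRDV1	TRDD2	TRDJ1	95.05	CALGDDIHPLPNTDKLIF
pt3	Tgd_LGLL	symptomatic	0.65	TRG	TRGV3		TRGJ1/2	83.82	CATWDRYKKLF
pt3	Tgd_LGLL	symptomatic	0.65	TRD	TRDV5	TRDD3	TRDJ1	93.23	CAASAIGSRGTDKLIF
pt4	Tgd_LGLL	symptomatic	0.66	TRG	TRGV4		TRGJ1/2	61.61	CATWDGPSMDYYKKLF
pt4	Tgd_LGLL	symptomatic	0.66	TRG	TRGV8		TRGJP1	18.89	CATWDRGGTTGWFKIF
pt4	Tgd_LGLL	symptomatic	0.66	TRG	TRGV3		TRGJP2	5.63	CATWDRPDWIKTF
pt4	Tgd_LGLL	symptomatic	0.66	TRD	TRDV1	TRDD3	TRDJ1	92.98	CALGEAPLGDTHSDKLIF
pt5	Tgd_LGLL	symptomatic	0.45	TRG	TRGV2		TRGJP2	40.99	CATWDGPGSSDWIKTF
pt5	Tgd_LGLL	symptomatic	0.45	TRG	TRGV2		TRGJ1/2	35.66	CATWDGPSYYKKLF
pt5	Tgd_LGLL	symptomatic	0.45	TRG	TRGV8		TRGJ1/2	8.85	CATWDRWYYKKLF
pt5	Tgd_LGLL	symptomatic	0.45	TRD	TRDV1	TRDD2	TRDJ1	51.01	CALGELVGGPFNTDKLIF
pt5	Tgd_LGLL	symptomatic	0.45	TRD	TRDV1	TRDD3	TRDJ1	32.43	CALGERRGDTFGADKLIF
pt5	Tgd_LGLL	symptomatic	0.45	TRD	TRDV1	TRDD3	TRDJ1	14.97	CALGEPPPSLGESKLIF
pt6	Tgd_LGLL	symptomatic	0.26	TRG	TRGV2		TRGJ1/2	25.11	CATWDGRVNYYKKLF
pt6	Tgd_LGLL	symptomatic	0.26	TRG	TRGV2		TRGJP2	9.18	CATWDYCSDWIKTF
pt6	Tgd_LGLL	symptomatic	0.26	TRG	TRGV4		TRGJ1/2	7.12	CATWEKGKLLYKKLF
pt6	Tgd_LGLL	symptomatic	0.26	TRG	TRGV8		TRGJP2	6.40	CATWDSSDWIKTF
pt6	Tgd_LGLL	symptomatic	0.26	TRD	TRDV5	TRDD3	TRDJ1	17.89	CAATSSYWGIYTDKLIF
pt6	Tgd_LGLL	symptomatic	0.26	TRD	TRDV1	TRDD2	TRDJ1	9.72	CALGVLPPGVHKLIF
pt6	Tgd_LGLL	symptomatic	0.26	TRD	TRDV1	TRDD3	TRDJ1	9.01	CALGPFLPTGGYTDKLIF
pt6	Tgd_LGLL	symptomatic	0.26	TRD	TRDV1	TRDD2	TRDJ1	7.21	CALGEAAPYQPSYTDKLIF
pt6	Tgd_LGLL	symptomatic	0.26	TRD	TRDV8	TRDD3	TRDJ1	6.68	CAYRSSTLFPYWGIRPDKLIF
pt7	Tgd_LGLL	indolent	0.58	TRG	TRGV9		TRGJP	32.04	CALWEVEELGKKIKVF
pt7	Tgd_LGLL	indolent	0.58	TRG	TRGV9		TRGJ1/2	26.05	CALERGKLF
pt7	Tgd_LGLL	indolent	0.58	TRG	TRGV9		TRGJP	22.93	CALWEVRELGKKIKVF
pt7	Tgd_LGLL	indolent	0.58	TRD	TRDV2	TRDD3	TRDJ1	60.70	CACDTLLGDTRSNTDKLIF
pt7	Tgd_LGLL	indolent	0.58	TRD	TRDV2	TRDD3	TRDJ3	38.88	CACDTLLGDTEDSWDTRQMFF
pt8	Tgd_LGLL	indolent	0.42	TRG	TRGV9		TRGJP	55.65	CALWEVRELGKKIKVF
pt8	Tgd_LGLL	indolent	0.42	TRD	TRDV2	TRDD3	TRDJ1	98.18	CACDTVVRGDLNTDKLIF
pt9	Tgd_LGLL	indolent	0.83	TRG	TRGV9		TRGJP	61.34	CALWEDRELGKKIKVF
pt9	Tgd_LGLL	indolent	0.83	TRD	TRDV2	TRDD3	TRDJ1	82.50	CACDTVGLGDTPSTDKLIF
pt9	Tgd_LGLL	indolent	0.83	TRD	TRDV2	TRDD3	TRDJ1	5.50	CACDVLGDTTDKLIF
pt10	Tgd_LGLL	indolent	0.34	TRG	TRGV9		TRGJP	20.75	CALWEVRELGKKIKVF
pt10	Tgd_LGLL	indolent	0.34	TRG	TRGV9		TRGJP	19.02	CALWEEELGKKIKVF
pt10	Tgd_LGLL	indolent	0.34	TRG	TRGV9		TRGJP	12.16	CALWDTELGKKIKVF
pt10	Tgd_LGLL	indolent	0.34	TRD	TRDV2	TRDD3	TRDJ3	39.73	CACDTSGGHPLSWDTRQMFF
pt10	Tgd_LGLL	indolent	0.34	TRD	TRDV2	TRDD3	TRDJ1	37.66	CACDTVGLGENGADKLIF
pt10	Tgd_LGLL	indolent	0.34	TRD	TRDV2	TRDD3	TRDJ1	16.96	CACDSILGALRRSPNTDKLIF
pt11	Tgd_LGLL	indolent	0.23	TRG	TRGV9		TRGJP	36.53	CALWEVEELGKKIKVF
pt11	Tgd_LGLL	indolent	0.23	TRD	TRDV2	TRDD3	TRDJ1	39.19	CACDTVEGWGIQAGDKLIF
pt11	Tgd_LGLL	indolent	0.23	TRD	TRDV2	TRDD3	TRDJ3	31.07	CACDSTGEISWDTRQMFF
pt11	Tgd_LGLL	indolent	0.23	TRD	TRDV2	TRDD3	TRDJ1	7.25	CACDTLGDTDKLIF
pt11	Tgd_LGLL	indolent	0.23	TRD	TRDV2	TRDD3	TRDJ3	5.40	CACDTVRTGGYAWDTRQMFF
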