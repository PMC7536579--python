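variant	original_class	zone	exon	gnomad_count	co_occurring_pathogenic	registry_id	source
p.Ala276Asp	4	DAMAGING_MODY	5	0	False	NORWAY	narrative
p.Tyr322Cys	3	INTERMEDIATE_T2D_RISK	5	9	False	NORWAY	partial
p.Thr354Met	3	INTERMEDIATE_T2D_RISK	6	7	False	NORWAY	narrative
p.Thr441Lys	3	INTERMEDIATE_T2D_RISK	7	18	True	NORWAY	narrative
p.Asp526Asn	3	DAMAGING_MODY	8	5	False	NORWAY	narrative
p.His582Arg	3	DAMAGING_MODY	10	14	False	NORWAY	narrative
p.Ala586Thr	2	DAMAGING_MODY	10	20	False	NORWAY	partial
p.Gly31Asp	2	BENIGN	1	1200	False	NORWAY	constructed
p.Glu48Lys	2	BENIGN	2	60	False	NORWAY	constructed
p.Ala97Val	1	BENIGN	2	500	False	NORWAY	constructed
p.Ala98Val	2	INTERMEDIATE_T2D_RISK	2	250	False	NORWAY	constructed
p.Gln100Lys	2	BENIGN	2	350	False	NORWAY	constructed
p.Arg114His	2	INTERMEDIATE_T2D_RISK	2	40	False	NORWAY	constructed
p.Leu389Val	2	BENIGN	6	150	False	NORWAY	constructed
p.Ser487Asn	2	INTERMEDIATE_T2D_RISK	7	300	False	NORWAY	constructed
p.Met490Thr	2	BENIGN	8	200	False	NORWAY	constructed
p.His514Arg	2	BENIGN	8	90	False	NORWAY	constructed
p.Thr515Lys	2	BENIGN	8	45	False	NORWAY	constructed
p.His577Asp	2	BENIGN	10	25	False	NORWAY	constructed
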