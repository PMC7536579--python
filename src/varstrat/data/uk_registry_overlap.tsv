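variant	original_class	zone	exon	gnomad_count	co_occurring_pathogenic	registry_id	source
p.Asn62Ser	4	BENIGN	2	33	False	UK	narrative
p.Ala161Thr	4	BENIGN	3	12	False	UK	narrative
p.Ala174Val	4	INTERMEDIATE_T2D_RISK	3	46	False	UK	partial
p.Gly606Ser	4	BENIGN	10	12	False	UK	narrative
p.His469Tyr	4	BENIGN	7	32	True	UK	narrative
p.Pro291Ser	4	INTERMEDIATE_T2D_RISK	5	58	False	UK	partial
p.Asp526Asn	4	DAMAGING_MODY	8	5	False	UK	narrative
p.Gly47Arg	4	BENIGN	2	1	False	UK	partial
p.Met412Thr	4	BENIGN	7	2	False	UK	partial
p.Thr10Met	4	INTERMEDIATE_T2D_RISK	1	2	False	UK	partial
p.Arg131Gln	4	DAMAGING_MODY	3	2	False	UK	partial
p.Arg171Gln	5	DAMAGING_MODY	3	0	False	UK	constructed
p.Gly288Arg	5	DAMAGING_MODY	5	1	False	UK	constructed
p.Pro379Thr	4	DAMAGING_MODY	6	0	False	UK	constructed
p.Arg200Trp	5	DAMAGING_MODY	4	0	False	UK	constructed
p.Leu107Arg	5	DAMAGING_MODY	2	0	False	UK	constructed
p.Tyr218Cys	4	DAMAGING_MODY	4	1	False	UK	constructed
p.Arg263Cys	5	DAMAGING_MODY	4	2	False	UK	constructed
p.Val133Met	4	DAMAGING_MODY	3	0	False	UK	constructed
p.Ile27Leu	1	BENIGN	1	5000	False	UK	constructed
p.Gly31Asp	2	BENIGN	1	1200	False	UK	constructed
p.Gln100Lys	2	BENIGN	2	350	False	UK	constructed
p.Arg114His	2	BENIGN	2	40	False	UK	constructed
p.Leu389Val	2	BENIGN	6	150	False	UK	constructed
p.Ser487Asn	2	BENIGN	7	300	False	UK	constructed
p.Met490Thr	2	BENIGN	8	200	False	UK	constructed
p.His514Arg	2	BENIGN	8	90	False	UK	constructed
p.Thr515Lys	2	BENIGN	8	45	False	UK	constructed
p.His577Asp	2	BENIGN	10	25	False	UK	constructed
p.Glu48Lys	2	BENIGN	2	60	False	UK	constructed
p.Ala97Val	2	BENIGN	2	500	False	UK	constructed
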