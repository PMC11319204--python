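criterion	label	weight	ad_only
c1	de_novo_confirmed	1	1
c2	gnomad_lof_constraint	1	1
c3	gnomad_missense_constraint	1	1
c4	multiple_unrelated_cases	1	0
c5	cosegregation_additional_family	1	0
c6	functional_evidence	1	0
c7	phenotype_specificity	1	0
c8	severe_variant_impact	1	0
c9	animal_model	0	0
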