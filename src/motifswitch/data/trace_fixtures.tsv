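unit_id	family	motif_start	motif_end	phospho_position	expected_motif_origin	expected_phospho_origin	expected_class	fasta
cdkn1b_like	SH3	41	44	51	CAEEL	RATUS	motif-first	trace_fixture_motif_first.fasta
tau_like	SH3	41	44	51	XENTR	DROME	phospho-first	trace_fixture_phospho_first.fasta
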