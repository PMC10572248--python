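strain	treatment	time	position	ref_base	gene_name	combined_frequency_pct	is_nonsynonymous
D2	PBS	14	4405	A	mt-Nd2	8.9	False
D2	PBS	14	11879	T	mt-Nd5	2.8	False
D2	V2O5	14	11879	T	mt-Nd5	8.1	False
B6	PBS	14	13052	T	mt-Nd5	3.0	False
B6	V2O5	14	14992	C	mt-Cytb	1.3	True
D2	V2O5	112	1054	G	mt-Tv	2.7	False
D2	PBS	112	2781	G	mt-Nd1	10.3	True
B6	V2O5	112	5228	G	mt-Tc	7.2	False
B6	V2O5	112	9214	T	mt-Co3	4.1	True
B6	V2O5	112	9461	T	mt-Nd3	26.0	False
D2	PBS	112	11879	T	mt-Nd5	20.2	False
B6	V2O5	112	13270	A	mt-Nd5	1.1	True
D2	V2O5	112	15446	A	D-loop	1.4	False
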