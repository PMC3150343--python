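sample_id	genomic_grade	mean_rank_g3set	mean_rank_g1set	score	n_used_g3set	n_used_g1set	tie_flag
sampleA	G3	12.5	2.5	0.625	8	4	False
sampleB	G1	4.5	14.5	-0.625	8	4	False
sampleC	G3	8.5	7.5	0.0625	8	4	False
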