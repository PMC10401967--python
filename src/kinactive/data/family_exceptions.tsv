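gene_label	family	skip_saltbridge	skip_actloopct
OTHER_WNK1	OTHER	1	0
OTHER_WNK2	OTHER	1	0
OTHER_WNK3	OTHER	1	0
OTHER_WNK4	OTHER	1	0
TKL_MAP3K12	TKL	1	0
TKL_MAP3K13	TKL	1	0
OTHER_HASPIN	OTHER	0	1
OTHER_TP53RK	OTHER	0	1
OTHER_PKDCC	OTHER	0	1
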