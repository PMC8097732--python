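run_id	condition	time_min	replicate	total_reads	mapped_reads
SRR3488627	dormant	0	1	7395066	243
SRR3488623	dormant	0	2	9593083	349
SRR3488631	no_nacl	30	1	11077704	414
SRR3488628	no_nacl	30	2	8808097	566
SRR3488632	no_nacl	60	1	10264883	785
SRR3488629	no_nacl	60	2	10487594	823
SRR3488633	no_nacl	90	1	12877261	1141
SRR3488630	no_nacl	90	2	8069190	683
SRR3488624	nacl	30	1	10215022	462
SRR3488622	nacl	30	2	10294457	882
SRR3488634	nacl	60	1	9182674	760
SRR3488625	nacl	60	2	9468524	530
SRR3488635	nacl	90	1	12497964	813
SRR3488626	nacl	90	2	9377023	712
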