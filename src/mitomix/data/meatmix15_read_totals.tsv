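replicate	clean_reads	mito_reads
R1	77978481	331866
R2	80207468	222702
R3	94898093	267495
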