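sample	total_raw_reads	total_clean_reads
control	106975508	99081102
FUS_R521H	108244484	99842418
FUS_P525L	92527778	85427768
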