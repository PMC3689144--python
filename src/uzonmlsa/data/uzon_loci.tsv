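# The eight protein-coding loci of the T. uzonensis MLSA scheme and their
# aligned fragment lengths (nt). Concatenate length = 8003 nt.
locus	aligned_length
gyrB	1111
lepA	1264
leuS	1040
pyrG	1204
recA	739
recG	1227
rplB	507
rpoB	911
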