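# Nucleotide differences between the allele pairs that distinguish the
# single-locus-variant (SLV) sequence-type pairs of the Uzon Caldera
# T. uzonensis dataset. Sparse: only the published SLV pairs are recorded.
locus	allele_a	allele_b	nt_diff
pyrG	13	14	10
pyrG	6	15	13
lepA	1	7	1
rpoB	3	7	2
recG	9	12	1
lepA	4	8	1
lepA	9	10	6
lepA	11	12	1
lepA	1	13	1
recG	14	15	1
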