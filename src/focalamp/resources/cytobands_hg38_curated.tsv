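# Curated (synthetic subset) cytoband table for hg38: approximate coordinates
# of a handful of well-known oncogene-bearing bands, for convenience in
# cytoband-level aggregation. NOT a complete karyotype; supply a full
# UCSC-style cytoband table for genome-wide band analyses.
# Coordinates 1-based inclusive.
cytoband	chrom	start	end
6p21	6	30500000	46200000
7p11	7	50000001	60100000
7q31	7	107800001	121100000
8q24	8	116700001	145138636
10q26	10	119100001	133797422
11q13	11	63400001	77100000
12p12	12	19800001	27800000
12q15	12	67300001	71100000
17q12	17	36100001	39900000
17q21	17	39900001	50200000
19q12	19	28100001	31900000
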