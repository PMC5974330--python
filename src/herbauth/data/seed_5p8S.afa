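>seed_5p8S_0
TGTATTGGCGTCTTGTTCGGAATCGATACATACTGGGGAGTAGTACCTACCAAGTCTGTT
>seed_5p8S_1
TGTCTGGGCGTCTTGTCCGGAATCGCTACATACTGGCGAGTAGTACTTACCAAGTCTGTT
>seed_5p8S_2
CGTCTTGGCGTCTTGTTCGGAATCGCTACATACTGGCGACTGGTACCTACCAAGTCTGTT
>seed_5p8S_3
TGTCTTGGCGTCTTGGTCGGAAACGCTACATACTGGCGAGTAGTACCTAGCAAGTCTGTT
>seed_5p8S_4
TGTCTTGGCGTCTTGTTCGGAATCGCTACATAGTGGCGAGTAATACTTACCAAGTCTGTT
>seed_5p8S_5
AGTCTTGGCGTCTTGTTCTGTATCGCTACATACTGGCGAGTAGTACCTACCAAGTCTGTT
>seed_5p8S_6
TGTCTTGGCGTCTTGTTCGGAATCGATACATACTGGCGAGTAGTTCCTAGCAAGTCTGTT
>seed_5p8S_7
TGTCTTGGCGTCTTGTTCCGAATCGCTAGATACTGGCGAGTCGTACCTACCAAGTCTGTT
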