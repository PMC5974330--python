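>seed_28S_0
ACGATGGCTTGAAGCCACACCTTATCGAATTCGGTCGTCACTTTAAATTGTCGTACTACC
>seed_28S_1
ACGATGGCTTGAATCCACAGCTTCTCGAATTCGATCGTCACCTTAAATTGTCGTGCTACC
>seed_28S_2
ACGCTGGCTTGAATCCACAGCTTATCGAATTCGATCGTCACCTTAAATTGTCGTGCTACC
>seed_28S_3
ACGATGGATTGAATCCACAGCTTATCGAATTCGGTCGTCAACTTAAATTTTCGTACTACC
>seed_28S_4
ACGATGGCTTGAATCCGCAGCTTATCGAATTTGGTCGTCACCTTAAATCGTCGTACTACC
>seed_28S_5
CCGATGGCTTGAATCCACAGCTTATCGAATTCGGACGTCACCTCAAATTGTCGTACTACC
>seed_28S_6
CCGATGGCTTGAATCCACAGTTTATCGGATTCGGTCGTCACCTTAAATTGTCGTACTACC
>seed_28S_7
ATGATGGCTTGAATCCACAGCTTATCGGATTCGGACGTCACCTTAAATTGTCGTACTACC
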