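sample_id	family_id	group
1	Full-sib1	high
2	Full-sib1	low
3	Full-sib2	high
4	Full-sib2	low
5	Half-sib1	high
6	Half-sib1	low
7	Half-sib2	high
8	Half-sib2	low
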