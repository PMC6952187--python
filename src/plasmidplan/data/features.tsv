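# Starter feature database: a small set of widely used short elements.
# name	sequence
T7_promoter	TAATACGACTCACTATAG
SP6_promoter	ATTTAGGTGACACTATAG
lac_operator	AATTGTGAGCGGATAACAATT
RBS_B0034	AAAGAGGAGAAA
His6_tag	CACCATCACCATCACCAT
FLAG_tag	GATTACAAGGATGACGACGATAAG
Strep_tag_II	TGGAGCCACCCGCAGTTCGAAAAA
M13_fwd	GTAAAACGACGGCCAGT
M13_rev	CAGGAAACAGCTATGAC
HA_tag	TACCCATACGATGTTCCAGATTACGCT
Myc_tag	GAACAAAAACTCATCTCAGAAGAGGATCTG
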