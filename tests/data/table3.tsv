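unigene_id	cold	drought	salinity
comp22423_c0_seq1	Yes	Yes	Yes
comp24732_c0_seq2	Yes	No	No
comp25430_c0_seq1	Yes	No	No
comp28513_c0_seq1	Yes	No	No
comp37332_c0_seq1	Yes	Yes	Yes
comp38200_c0_seq1	Yes	No	No
comp38390_c0_seq5	No	Yes	Yes
comp39646_c0_seq2	Yes	Yes	Yes
comp39900_c0_seq1	No	Yes	Yes
comp39917_c0_seq1	No	No	Yes
comp41481_c0_seq2	Yes	No	No
comp42998_c0_seq1	Yes	No	Yes
comp43037_c0_seq1	Yes	No	Yes
comp43634_c0_seq1	No	Yes	Yes
comp45199_c0_seq1	No	Yes	Yes
comp45561_c0_seq1	Yes	No	No
comp47037_c0_seq1	No	Yes	Yes
comp47415_c0_seq1	Yes	No	Yes
comp47471_c0_seq6	No	Yes	Yes
comp47482_c0_seq2	Yes	No	Yes
comp47503_c0_seq6	Yes	No	Yes
comp47673_c0_seq3	Yes	No	No
comp47694_c0_seq2	Yes	No	No
comp48118_c0_seq4	No	Yes	Yes
comp50179_c0_seq1	Yes	Yes	Yes
comp51180_c1_seq11	Yes	No	Yes
comp81788_c0_seq1	Yes	No	No
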