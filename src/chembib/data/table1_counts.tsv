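# Published summary-table count columns used as worked-example inputs.
# anst_pol = analytical-study/pollutant search (grand total 413,007 counts,
# 19,776 substances); biol_occur = biological-study search with the same
# substance list (grand total 9,251,975 counts).
row	casrn	anst_pol_counts	biol_occur_counts
grand_total		413007	9251975
top_10		36128	950454
top_100		140527	3303278
top_200		190759	4469288
top_300		222788	5214655
top_500		262875	6166490
lead	7439-92-1	6224	73043
cadmium	7440-43-9	4692	82544
p,p'-DDT	50-29-3	1571	15534
2,3,7,8-TCDD	1746-01-6	743	10066
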