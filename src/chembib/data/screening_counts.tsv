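# Published screening arithmetic: size of the raw deduplicated substance
# list, manual exclusions, the final analysis list, and the reduction
# applied before the inventory-overlap comparison.
quantity	value
initial_casrns	23458
excluded_casrns	3682
final_casrns	19776
overlap_prefilter_removed	3630
overlap_reference_casrns	16146
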