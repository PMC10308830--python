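# Published inventory-overlap counts: overlap of the reduced analysis
# list (pesticides and pharmaceuticals removed) with each jurisdictional
# inventory, and the declared (real) inventory sizes.
inventory	overlap_count	declared_size
TSCA	3499	67950
IECSC	2974	37100
REACH	1576	16760
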