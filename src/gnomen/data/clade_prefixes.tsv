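# Offline clade-prefix table for ToLID construction.
# Columns: clade_keyword <TAB> prefix <TAB> vertebrate_flag (0/1)
# Vertebrate clades use a single rank letter (VGP legacy); others use
# rank letter + clade letter.  Extend or override with a user TSV.
dicot	dd	0
dicot-brassicales	dd	0
dicot-rosid	dr	0
dicot-asterid	da	0
liliopsida	ll	0
liliopsida-poales	lp	0
insect-diptera	id	0
insect-coleoptera	ic	0
insect-hymenoptera	iy	0
insect-lepidoptera	il	0
mammal	m	1
bird	b	1
fish	f	1
amphibian	a	1
reptile	r	1
shark	s	1
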