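# Per-species conversion metadata, one section per legacy scheme.
# The ToLID is built from genus/species plus the clade prefix letters;
# sample_name overrides (or supplies) the variety when the legacy scheme
# does not encode it; `chromosome` supplies one for schemes lacking it.

[brassica_bna]
clade_prefix = dd
genus = Brassica
species = napus

[soybean_glyma]
clade_prefix = dr
genus = Glycine
species = max
sample_name = WM82

[barley_horvu_barke]
clade_prefix = lp
genus = Hordeum
species = vulgare

[wheat_traes]
clade_prefix = lp
genus = Triticum
species = aestivum

[grape_vitvi]
clade_prefix = dr
genus = Vitis
species = vinifera
sample_name = PN40024

[honeycrisp_hap]
clade_prefix = dr
genus = Malus
species = domestica
chromosome = 3
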