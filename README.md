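# gnomen

Standardized nomenclature for genome assemblies and gene models: generate,
parse, validate and inter-convert identifiers — including a dozen legacy
community schemes — and batch-rename GFF3/FASTA annotation files to the
standardized scheme with full provenance.

## The problem

Every crop community historically invented its own identifier pattern
(`TraesCS3D02G273600`, `Zm00001eb000050`, `C01p010030.1_BnaDAR`, ...), and
assembly names in public repositories are worse (`TAIR10.1`, `ONTmin_IT4`,
`Ler Assembly`).  Inconsistent naming breaks pipelines, makes assemblies hard
to find, and severs the link between a gene model and the assembly version it
was predicted on.  `gnomen` implements a FAIR-minded dotted convention in
which every field is machine-parseable and human-readable:

```
assembly name    <ToLID>.<variety>.<group>.<major>[.<minor>][.<extras>...]
gene-model ID    <ToLID>.<variety>[.<group>].<major>.<annotation>.<region><entity><number>[.<transcript>]
```

* **ToLID** — Tree-of-Life species code: rank+clade letters (one letter for
  vertebrates), `1 upper + ≤2 lower` genus letters, `1 upper + ≤3 lower`
  species letters (≤2 for vertebrates), optional sample number.
  `Malus domestica` → `drMalDome`.
* **region** — zero-padded chromosome digits plus optional subgenome letter
  (wheat `03D`) and/or haplotype tag (`3Hap1`), or a scaffold token.
* **entity** — `g` gene, `p` protein, `t` transcript, `pan` pan-gene,
  followed by a six-digit entity number; a trailing ordinal names one
  transcript of the gene.

For whom: genome database curators adopting the convention, assembly
submitters who need repository-safe names, and pipeline authors converting
legacy identifier tables or renaming whole annotations.

## Worked example

Convert a table of legacy gene-model identifiers, given per-species metadata
(the legacy strings rarely say which cultivar was sequenced):

```
$ gnomen convert --in examples/legacy_ids.txt --config examples/species.cfg
raw	scheme	new_assembly_id	new_gene_model_id	error
C01p010030.1_BnaDAR	brassica_bna	ddBraNapu.DAR.1.0	ddBraNapu.DAR.1.1.01C.p010030	
Glyma.01g000100.Wm82.a2.v1	soybean_glyma	drGlyMax.WM82.2.0	drGlyMax.WM82.2.1.01.g000100	
Horvu_BARKE_1H01G000300.1	barley_horvu_barke	lpHorVulg.BARKE.1.0	lpHorVulg.BARKE.1.1.01.g000300	
TraesCS3D02G273600	wheat_traes	lpTriAest.CS.1.0	lpTriAest.CS.1.1.03D.g273600	
Vitvi18g12230	grape_vitvi	drVitVini.PN40024.1.0	drVitVini.PN40024.1.1.18.g012230	
Honeycrisp_HAP1_v1.0.031896	honeycrisp_hap	drMalDome.Honeycrisp.1.0.HAP1	drMalDome.Honeycrisp.1.1.3Hap1.g031896	
```

Reading the wheat row: `TraesCS3D02G273600` is Chinese Spring (`CS`),
chromosome 3, subgenome D, gene 273600.  The converted
`lpTriAest.CS.1.1.03D.g273600` keeps every one of those facts (the entity
number's integer value never changes, only its padding) and adds what was
missing: the species code, the assembly version (1) and the annotation
version (1) the model belongs to.  Soybean's legacy token `a2` becomes
assembly version `2.0`; apple's phased haplotype `HAP1` moves into the
region (`3Hap1`).

Other everyday calls:

```
$ gnomen tolid --genus Malus --species domestica --clade dicot-rosid
drMalDome
$ gnomen validate "drMal Dome.1"        # exit code 1, WHITESPACE error
$ gnomen rename-gff --in old.gff3 --out new.gff3 --map-out map.tsv \
    --assembly-name drVitVini.PN40024.1.0 --keep-old
```

`rename-gff` numbers genes sequentially along each chromosome
(10, 20, 30, ... by default, so neighbouring numbers mean neighbouring
genes), renames transcripts as `<gene>.<ordinal>`, updates `Parent`
attributes, records the old ID under `Dbxref=Legacy:...`, and writes an
old→new rename map that `rename-fasta` applies to matching FASTA headers.
Everything except ID/Parent/Dbxref values is byte-preserved.

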