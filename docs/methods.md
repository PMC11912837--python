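# Methods

## The identifier model

An assembly name is a sequence of period-separated fields:
`<ToLID>.<sample>.<group>.<major>[.<minor>][.<extras>...]`.  Period is the
sole field separator; hyphen and underscore are legal inside tokens (tokens
match `[A-Za-z0-9_-]+`), which is what real community names require
(`Col-CC`, `C_sonorensis_v3_redundans`).  The `strict` grammar profile
demands the four mandatory fields — species code, individual, sequencing
group, version — because different groups do assemble the same cultivar and
the name must disambiguate them.  The `compat` profile tolerates a missing
group and a missing minor version, since the converted-legacy style omits
both.  Field roles are resolved positionally: the third field is the group
unless it matches `v?\d+`, in which case it is the version; the single
all-digit token immediately after the major version is the minor; every
remaining token is an opaque "extra" (haplotype tag, `organelles`, appended
legacy name).  A consequence, documented rather than hidden: an extra may
not be purely numeric unless a minor version is present, or it would be read
as the minor.

A gene-model identifier appends `<annotation>.<region>.<entity>` (plus an
optional transcript ordinal) to the assembly prefix, and the prefix carries
the **major version only** — `drVitVini.PN40024.1.1.18.g012230` is assembly
major 1, annotation 1.  Parsing anchors from the right (entity token, then
region, then annotation), so the assembly prefix never becomes ambiguous
with the annotation field.  The region is either zero-padded chromosome
digits with optional subgenome letter and/or `Hap<n>` tag, or a scaffold
token.  Chromosome padding is width-2 on emission by default but any width
is accepted on parse, and the observed width is retained so that
parse∘serialize is byte-identical.

The `..` empty-slot dialect: some converted tables leave an empty dotted
slot between region and entity when no subgenome is present
(`...01..g000100`).  The parser accepts exactly one such empty slot and
normalizes it to "no subgenome"; the serializer never emits it unless the
`table3` dialect is requested.  This keeps canonical output unambiguous
while still round-tripping the published tables.

## ToLID construction

Genus and species abbreviation is purely mechanical (lowercase, then
first-letter-uppercase with a 2/3-letter budget; vertebrates get one fewer
species letter and a single prefix letter, both VGP legacy).  Epithets
shorter than the budget are used whole — `max` → `Max` — following the
attested codes.  Clade prefixes come from a bundled offline TSV seeded with
the attested plant/insect prefixes (`dd`, `dr`, `lp`, `id`) plus the
single-letter vertebrate groups; there is deliberately no network lookup of
the live registry, so the table is user-extensible and an unknown clade is
an error that tells the user to supply the letters directly.  Consequently
no global-uniqueness guarantee is made.  Sample numbers are supported but
opt-in: every attested converted assembly name omits them.

## Legacy schemes and conversion

Each legacy scheme is a regex with named groups plus a literal template;
`parse` fills a `LegacyRecord` and `assemble` re-concatenates it, so
losslessness is structural, not tested-in.  Detection order is fixed
(most-specific first) and anything unmatched is `unknown` — no fuzzy
matching.  Two decompositions deserve comment:

* Barley chromosome tokens (`1H`, `6H`) carry a constant genome designator
  `H`; barley is diploid, so `H` distinguishes nothing within the assembly.
  It is captured as a scheme-specific `genome_letter` (preserving lossless
  reassembly) and dropped on conversion, unlike wheat's true subgenome
  letters (A/B/D), which are preserved verbatim.
* Single-letter haplome designations (GDR's `ch10A`) occupy the same
  region slot as a subgenome letter on conversion; `HAP<n>`-style tokens are
  normalized to `Hap<n>`.

Conversion combines a record with a per-species `ConversionConfig`.  Version
inference follows the attested tokens (`a2`→2, `r3`→3, `v1.0`→1, `5.0`→5);
tokens that are annotation-side bookkeeping of the old scheme (wheat's `02`
infix) are stored as annotation tokens and never touch the assembly version.
The new annotation ordinal is configuration (default 1), never inferred.
Entity numbers convert by integer value and are re-padded to the configured
width (default 6); chromosomes from legacy records are re-padded to the
configured width (default 2), while a chromosome supplied through the config
(for schemes that never encoded one) is trusted in its given display form —
the two published conventions differ on exactly this point, and this rule
reproduces both.  Records lacking an entity letter are gene models (`g`);
legacy transcript suffixes are dropped because the converted ID names the
gene model itself.  Converted assembly names use the table style:
`<major>.<minor>` with minor defaulting to 0, no group unless configured
(strict validation then reports a MISSING_GROUP *warning*, surfacing the
convention's own tension rather than hiding it), and any haplotype token
appended verbatim as an extra field.

## Annotation rewriting

`rewrite_gff3` is a deliberate line-level edit rather than a parse/re-emit
through an object model: the contract is that only `ID`, `Parent` and
(optionally) `Dbxref` values change and every other byte — column order,
attribute order, spacing, comments — survives.  Gene numbering sorts by
(natural seqid order, start ascending, end descending, ID) and assigns
`start, start+step, ...` per seqid (defaults 10/10/width 6, leaving room for
later insertions); numbering uses the start coordinate regardless of strand,
because the point of sequential numbers is positional adjacency.  A seeded
random mode exists for communities that prefer position-free numbers.
Exceeding the width's capacity is an error suggesting a larger width, never
a silent wrap.  Transcript children (`mRNA`/`transcript`) get 1-based
ordinals by start position within their gene; no legacy canonical-transcript
designation is assumed or preserved.  Features on unplaced scaffolds get the
sanitized seqid token as their region and an independent numbering sequence;
non-gene top-level features pass through unrenamed unless an explicit
type→entity mapping is given.  `--detect-new` skips features whose ID
already parses as a new-scheme identifier, making rewriting idempotent.
FASTA header rewriting is the same philosophy: only the first token of
mapped headers changes; residues, order and wrapping are untouched
(verified in tests against Biopython-parsed residues, with gffutils as the
independent check of the rewritten GFF3 hierarchy).

## Synthetic data

`generate_fixture` emulates a plant-style nested annotation — gene → mRNA →
exon along each chromosome, random intergenic gaps (200–2000 bp), gene
lengths 300–3000 bp, random-nucleotide chromosome sequences — deterministic
given its seed.  It does **not** emulate overlapping genes, trans-splicing,
multi-parent features, attribute escaping or pseudo-molecule naming
variants, so passing tests demonstrate correctness of ordering, renaming,
conservation and referential integrity, not robustness to every GFF3 corner
case found in the wild.  Test and script problem sizes (≤ 50 genes per
fixture, 1000 random identifiers for round-trip properties) were chosen as
the smallest sizes at which ordering, per-seqid restarts and tie-breaking
are all exercised.

## Numerical/degenerate-input choices

* Entity number 0 is legal and serializes to `g000000`; overflow of the pad
  width is an error at construction time.
* ToLID sample numbers reject leading zeros (the sequence starts at 1).
* Validation (`validate_name`) is pure and never raises; findings are
  report entries with severities, and the taxonomy stop-list check matches
  whole dotted fields case-insensitively (repositories reject taxonomic
  names embedded in assembly names).  The serialized-length maximum is a
  parameter (default 100 characters) because repository limits are policy,
  not a universal constant.
* Empty inputs: an empty identifier is a single EMPTY error; an empty
  feature list yields an empty numbering map; a zero-sized fixture is a
  header-only GFF3.

## Known limitations

Scheme coverage is the cataloged set; related-but-different community
patterns (e.g. other Ensembl accession styles) detect as `unknown` by
design.  The apple ("Honeycrisp") converted assembly name is emitted as
`drMalDome.Honeycrisp.1.0.HAP1`, keeping the `<major>.<minor>` version slot
consistent with every other converted row; one published rendering of that
row instead shows the gene-ID-style `1.1` slot, which this package treats as
an inconsistency to normalize, not a dialect to reproduce.  No registry or
cross-organization uniqueness service is provided, and no biological
validation of metadata (whether a variety name is real) is attempted.
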