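"""Grammar, serialization and validation of new-scheme identifiers."""

import random

import pytest
from hypothesis import given, strategies as st

from gnomen.identifiers import (
    AnnotationVersion,
    AssemblyName,
    GeneModelID,
    IdentifierError,
    SeqRegion,
    ToLID,
    parse_assembly_name,
    parse_gene_model_id,
    report_to_jsonl,
    report_to_tsv,
    serialize_assembly_name,
    serialize_gene_model_id,
    validate_name,
)

from conftest import NEW_SCHEME_NAMES, random_assembly_name, random_gene_model_id


class TestToLID:
    @pytest.mark.parametrize(
        "code,rank,clade,genus,species,sample",
        [
            ("drMalDome", "d", "r", "Mal", "Dome", None),
            ("idCulSono", "i", "d", "Cul", "Sono", None),
            ("mBosTau1", "m", None, "Bos", "Tau", 1),
            ("lpTriAest", "l", "p", "Tri", "Aest", None),
        ],
    )
    def test_parse_fields(self, code, rank, clade, genus, species, sample):
        t = ToLID.parse(code)
        assert (t.rank_letter, t.clade_letter, t.genus_code, t.species_code, t.sample_number) == (
            rank,
            clade,
            genus,
            species,
            sample,
        )
        assert str(t) == code

    @pytest.mark.parametrize("bad", ["", "DRMalDome", "drmalDome", "drMal", "drMalDome01", "dr-MalDome"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(IdentifierError):
            ToLID.parse(bad)


class TestAssemblyNameParse:
    def test_haplotype_example(self):
        a = parse_assembly_name("drMalDome.gr.TGMGP.1.Hap1")
        assert str(a.tolid) == "drMalDome"
        assert a.sample_name == "gr"
        assert a.group == "TGMGP"
        assert (a.version_major, a.version_minor) == (1, None)
        assert a.extras == ("Hap1",)

    def test_appended_legacy_name(self):
        a = parse_assembly_name("idCulSono.KS.ABADRU.3.0.C_sonorensis_v3_redundans")
        assert (a.sample_name, a.group) == ("KS", "ABADRU")
        assert (a.version_major, a.version_minor) == (3, 0)
        assert a.extras == ("C_sonorensis_v3_redundans",)

    def test_compat_tolerates_missing_group(self):
        a = parse_assembly_name("ddBraNapu.DAR.1.0", profile="compat")
        assert a.group is None
        assert (a.version_major, a.version_minor) == (1, 0)

    def test_strict_requires_group(self):
        with pytest.raises(IdentifierError) as exc:
            parse_assembly_name("ddBraNapu.DAR.1.0", profile="strict")
        assert exc.value.code == "MISSING_GROUP"

    def test_empty_field_code(self):
        with pytest.raises(IdentifierError) as exc:
            parse_assembly_name("drMalDome..TGMGP.1")
        assert exc.value.code == "EMPTY_FIELD"

    def test_malformed_tolid_names_span(self):
        with pytest.raises(IdentifierError) as exc:
            parse_assembly_name("NotATolid.gr.TGMGP.1")
        assert exc.value.code == "TOLID"
        assert exc.value.span == (0, len("NotATolid"))

    def test_v_prefix_preserved(self):
        a = parse_assembly_name("drMalDome.gr.TGMGP.v3", profile="strict")
        assert a.has_v_prefix and a.version_major == 3
        assert serialize_assembly_name(a) == "drMalDome.gr.TGMGP.v3"


class TestAssemblyNameSerialize:
    def test_organelles_example(self):
        a = AssemblyName(
            tolid=ToLID.parse("drAraHypo"),
            sample_name="HighOil",
            group="TGMGP",
            version_major=1,
            version_minor=0,
            extras=("organelles",),
        )
        assert serialize_assembly_name(a) == "drAraHypo.HighOil.TGMGP.1.0.organelles"

    def test_haplotype_pair(self):
        for hap in ("Hap1", "Hap2"):
            a = AssemblyName(ToLID.parse("drMalDome"), "gr", group="TGMGP", version_major=1, extras=(hap,))
            assert serialize_assembly_name(a) == f"drMalDome.gr.TGMGP.1.{hap}"

    def test_compat_style_omits_group(self):
        a = parse_assembly_name("drMalDome.gr.TGMGP.1.Hap1")
        assert serialize_assembly_name(a, style="compat") == "drMalDome.gr.1.Hap1"

    def test_refuses_bad_tokens(self):
        with pytest.raises(IdentifierError):
            AssemblyName(ToLID.parse("drMalDome"), "has space", version_major=1)
        with pytest.raises(IdentifierError):
            AssemblyName(ToLID.parse("drMalDome"), "with.dot", version_major=1)

    @pytest.mark.parametrize("s", NEW_SCHEME_NAMES)
    def test_round_trip_published_names(self, s):
        assert serialize_assembly_name(parse_assembly_name(s, profile="compat")) == s


class TestGeneModelIDParse:
    def test_subgenome_row(self):
        g = parse_gene_model_id("ddBraNapu.DAR.1.1.01C.p010030")
        assert g.region.kind == "chromosome"
        assert (g.region.number, g.region.pad_width, g.region.subgenome) == (1, 2, "C")
        assert (g.entity_type, g.entity_number, g.entity_pad_width) == ("p", 10030, 6)
        assert g.annotation.value == 1
        assert g.assembly.version_major == 1 and g.assembly.version_minor is None

    def test_haplotype_row(self):
        g = parse_gene_model_id("drMalDome.Honeycrisp.1.1.3Hap1.g031896")
        assert (g.region.number, g.region.pad_width, g.region.haplotype) == (3, 1, "Hap1")
        assert g.region.subgenome is None
        assert (g.entity_type, g.entity_number) == ("g", 31896)

    def test_transcript_ordinal(self):
        g = parse_gene_model_id("drVitVini.PN40024.1.1.18.g012230.2")
        assert g.transcript_number == 2
        assert (g.region.number, g.entity_number) == (18, 12230)
        assert str(g).endswith(".2")

    def test_empty_slot_dialect_normalized(self):
        g = parse_gene_model_id("drGlyMax.WM82.2.1.01..g000100")
        assert g.region.subgenome is None
        assert serialize_gene_model_id(g) == "drGlyMax.WM82.2.1.01.g000100"
        assert serialize_gene_model_id(g, dialect="table3") == "drGlyMax.WM82.2.1.01..g000100"

    def test_unknown_entity_letter_lists_alphabet(self):
        with pytest.raises(IdentifierError) as exc:
            parse_gene_model_id("drMalDome.gr.1.1.01.q000100")
        assert "g, p, t, pan" in str(exc.value)

    def test_non_numeric_number(self):
        with pytest.raises(IdentifierError):
            parse_gene_model_id("drMalDome.gr.1.1.01.gABC")

    def test_scaffold_region(self):
        g = parse_gene_model_id("drMalDome.gr.1.1.scaffold_42.g000010")
        assert g.region.kind == "scaffold"
        assert g.region.number == "scaffold_42"


class TestGeneModelIDSerialize:
    def test_wheat_fields(self):
        g = GeneModelID(
            assembly=AssemblyName(ToLID.parse("lpTriAest"), "CS", version_major=1),
            annotation=AnnotationVersion(1),
            region=SeqRegion("chromosome", 3, pad_width=2, subgenome="D"),
            entity_type="g",
            entity_number=273600,
        )
        assert serialize_gene_model_id(g) == "lpTriAest.CS.1.1.03D.g273600"

    def test_zero_number(self):
        g = GeneModelID(
            assembly=AssemblyName(ToLID.parse("drMalDome"), "gr", version_major=1),
            annotation=AnnotationVersion(1),
            region=SeqRegion("chromosome", 1),
            entity_type="g",
            entity_number=0,
        )
        assert str(g).endswith("g000000")

    def test_overflow_refused(self):
        with pytest.raises(IdentifierError) as exc:
            GeneModelID(
                assembly=AssemblyName(ToLID.parse("drMalDome"), "gr", version_major=1),
                annotation=AnnotationVersion(1),
                region=SeqRegion("chromosome", 1),
                entity_type="g",
                entity_number=1234567,
                entity_pad_width=6,
            )
        assert exc.value.code == "OVERFLOW"

    def test_canonical_never_emits_empty_slot(self):
        rng = random.Random(5)
        for _ in range(200):
            s = serialize_gene_model_id(random_gene_model_id(rng))
            assert ".." not in s


class TestRoundTripProperties:
    def test_gene_model_identity_1000(self):
        """parse(serialize(x)) == x, and bytes survive a second pass, on 1000 seeded IDs."""
        rng = random.Random(20240901)
        for _ in range(1000):
            g = random_gene_model_id(rng)
            s = serialize_gene_model_id(g)
            g2 = parse_gene_model_id(s)
            assert g2 == g
            assert serialize_gene_model_id(g2) == s

    def test_assembly_identity(self):
        rng = random.Random(7)
        for _ in range(500):
            a = random_assembly_name(rng)
            s = serialize_assembly_name(a)
            assert parse_assembly_name(s, profile="compat") == a

    def test_gene_id_prefix_is_assembly_name(self):
        """Any accepted gene-model ID has a prefix accepted by the compat assembly grammar."""
        rng = random.Random(99)
        for _ in range(300):
            g = random_gene_model_id(rng)
            s = serialize_gene_model_id(g)
            prefix = ".".join(serialize_assembly_name(g.assembly).split("."))
            assert s.startswith(prefix + ".")
            parse_assembly_name(prefix, profile="compat")


class TestValidateName:
    def test_clean_name_empty_report(self):
        rep = validate_name("drMalDome.gr.TGMGP.1.Hap1")
        assert rep.valid and not rep.issues

    def test_whitespace_error(self):
        rep = validate_name("drMal Dome.gr.1")
        assert rep.has_errors
        assert any(i.code == "WHITESPACE" for i in rep.issues)

    def test_taxon_stop_list_warning(self):
        rep = validate_name("drMalDome.Malus.TGMGP.1", stop_list={"Malus"})
        codes = [(i.severity, i.code) for i in rep.issues]
        assert ("warning", "TAXON_TERM") in codes
        assert not rep.has_errors

    def test_length_limit_configurable(self):
        name = "drMalDome.gr.TGMGP.1." + "x" * 100
        assert validate_name(name).has_errors
        assert not validate_name(name, max_length=200).has_errors

    def test_charset_violation(self):
        rep = validate_name("drMalDome.gr#bad.1")
        assert any(i.code == "CHARSET" for i in rep.issues)

    def test_strict_profile_warns_on_missing_group(self):
        rep = validate_name("ddBraNapu.DAR.1.0", profile="strict")
        assert not rep.has_errors
        assert any(i.code == "MISSING_GROUP" and i.severity == "warning" for i in rep.issues)

    def test_strict_profile_accepts_gene_model_ids(self):
        assert not validate_name("lpTriAest.CS.1.1.03D.g273600", profile="compat").has_errors

    def test_validator_is_pure(self):
        args = ("drMal Dome.gr.1", "insdc", ("Malus",), 100)
        a = validate_name(*args)
        b = validate_name(*args)
        assert a == b

    def test_report_serializations(self):
        reps = [validate_name("drMal Dome.gr.1"), validate_name("drMalDome.gr.TGMGP.1")]
        tsv = report_to_tsv(reps)
        assert "WHITESPACE" in tsv and tsv.count("\n") >= 3
        jsonl = report_to_jsonl(reps)
        assert jsonl.count("\n") == 2


class TestGrammarShape:
    def test_minimal_strict_name_has_four_fields(self):
        a = parse_assembly_name("drMalDome.gr.TGMGP.1", profile="strict")
        assert len(a.fields()) == 4
        with pytest.raises(IdentifierError):
            parse_assembly_name("drMalDome.gr.1", profile="strict")

    def test_transcript_grammar_has_six_semantic_slots(self):
        assert len(GeneModelID.FIELD_SLOTS) == 6

    def test_default_entity_width_is_six(self):
        g = parse_gene_model_id("drMalDome.gr.1.1.01.g000010")
        assert g.entity_pad_width == 6

    @given(st.integers(min_value=0, max_value=999999), st.integers(min_value=1, max_value=9))
    def test_entity_token_width_invariant(self, number, annotation):
        g = GeneModelID(
            assembly=AssemblyName(ToLID.parse("drMalDome"), "gr", version_major=1),
            annotation=AnnotationVersion(annotation),
            region=SeqRegion("chromosome", 1),
            entity_type="g",
            entity_number=number,
        )
        assert len(g.entity_token()) == 7  # "g" + 6 digits
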