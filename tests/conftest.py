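"""Shared corpus of published example identifiers and random generators."""

from __future__ import annotations

import random
import re
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from gnomen import (
    AnnotationVersion,
    AssemblyName,
    GeneModelID,
    SeqRegion,
    ToLID,
    load_species_configs,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

REPO = Path(__file__).resolve().parent.parent
EXAMPLES = REPO / "examples"

# Converted-table worked examples: legacy gene ID, scheme, new assembly ID,
# new gene-model ID (canonical), and whether the published row uses the
# empty-slot "01.." dialect.
TABLE3 = [
    ("C01p010030.1_BnaDAR", "brassica_bna", "ddBraNapu.DAR.1.0", "ddBraNapu.DAR.1.1.01C.p010030", False),
    ("Glyma.01g000100.Wm82.a2.v1", "soybean_glyma", "drGlyMax.WM82.2.0", "drGlyMax.WM82.2.1.01.g000100", True),
    ("Horvu_BARKE_1H01G000300.1", "barley_horvu_barke", "lpHorVulg.BARKE.1.0", "lpHorVulg.BARKE.1.1.01.g000300", True),
    ("TraesCS3D02G273600", "wheat_traes", "lpTriAest.CS.1.0", "lpTriAest.CS.1.1.03D.g273600", False),
    ("Vitvi18g12230", "grape_vitvi", "drVitVini.PN40024.1.0", "drVitVini.PN40024.1.1.18.g012230", False),
    ("Honeycrisp_HAP1_v1.0.031896", "honeycrisp_hap", "drMalDome.Honeycrisp.1.0.HAP1", "drMalDome.Honeycrisp.1.1.3Hap1.g031896", False),
]

# Legacy identifiers attested in community catalogs, with their scheme.
LEGACY_GENE_EXAMPLES = [
    ("C01p010030.1_BnaDAR", "brassica_bna"),
    ("HORVU.MOREX.r3.6HG0548430", "barley_horvu_morex"),
    ("Horvu_BARKE_1H01G000300.1", "barley_horvu_barke"),
    ("TraesCS3D02G273600", "wheat_traes"),
    ("Vitvi18g12230", "grape_vitvi"),
    ("Zm00001eb000050", "maize_zm"),
    ("SORBI_3006G095600", "sorghum_sobic"),
    ("Sobic.006G095600", "sorghum_sobic"),
    ("Glyma.01g000100.Wm82.a2.v1", "soybean_glyma"),
    ("Maldo.hc.v1a1.ch10A.g00001.t1", "gdr_maldo"),
    ("Honeycrisp_HAP1_v1.0.031896", "honeycrisp_hap"),
    ("At1g01010.1_TAIR12", "tair_agi"),
    ("At1g01010_TAIR12", "tair_agi"),
    ("Fv.01g000010", "fragaria_fv"),
]

LEGACY_ASSEMBLY_EXAMPLES = [
    ("Maldo.hc.v1.ch10A", "gdr_maldo_assembly"),
    ("AST_PRJEB5043_v1", "ensembl_ast_assembly"),
    ("Wm82.a6.v1", "soy_wm82_assembly"),
    ("MorexV3_pseudomolecules_assembly", "morex_assembly"),
    ("C_sonorensis_v2_redundans", "culicoides_assembly"),
    ("Zm-B73-REFERENCE-NAM-5.0", "maize_zm_assembly"),
    ("At3702.Col-0.Col-CC.v2", "tair_assembly"),
    ("ddAraThal4.1", "vgp_style"),
]

# Chaotic repository names with no cataloged scheme: must detect as unknown,
# never be guessed at.
UNKNOWN_EXAMPLES = [
    "",
    "TAIR10.1",
    "Tanz-1.10024.PacbioHiFiAssembly",
    "ASM2311539v1",
    "6137",
    "AT5784.Ty-1.PacBio",
    "AtA1-141.20181003",
    "Arabidopsis_thaliana_Ler",
    "Ath.Ler-0.MPIPZ.v1.0",
    "ONTmin_IT4",
]

# New-scheme hypothetical names that must round-trip byte-identically.
NEW_SCHEME_NAMES = [
    "drAraHypo.HighOil.TGMGP.1.0.organelles",
    "drMalDome.gr.TGMGP.1.Hap1",
    "drMalDome.gr.TGMGP.1.Hap2",
    "idCulSono.KS.ABADRU.3.0.C_sonorensis_v3_redundans",
]

# ToLIDs attested in worked examples: code, clade prefix, genus, species epithet.
ATTESTED_TOLIDS = [
    ("ddBraNapu", "dd", "Brassica", "napus"),
    ("drGlyMax", "dr", "Glycine", "max"),
    ("lpHorVulg", "lp", "Hordeum", "vulgare"),
    ("lpTriAest", "lp", "Triticum", "aestivum"),
    ("drVitVini", "dr", "Vitis", "vinifera"),
    ("drMalDome", "dr", "Malus", "domestica"),
    ("idCulSono", "id", "Culicoides", "sonorensis"),
    ("drAraHypo", "dr", "Arachis", "hypogaea"),
]


@pytest.fixture(scope="session")
def species_configs():
    return load_species_configs(EXAMPLES / "species.cfg")


@pytest.fixture(scope="session")
def table3_ids():
    return [row[0] for row in TABLE3]


# ---------------------------------------------------------------------------
# seeded random generators for round-trip properties
# ---------------------------------------------------------------------------

_LOWER = "abcdefghijklmnopqrstuvwxyz"
_UPPER = _LOWER.upper()
_TOKEN_CHARS = _LOWER + _UPPER + "0123456789_-"


def _letters(rng: random.Random, alphabet: str, n: int) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def random_tolid(rng: random.Random) -> ToLID:
    return ToLID(
        rank_letter=rng.choice(_LOWER),
        clade_letter=rng.choice([None, rng.choice(_LOWER)]),
        genus_code=rng.choice(_UPPER) + _letters(rng, _LOWER, rng.randint(0, 2)),
        species_code=rng.choice(_UPPER) + _letters(rng, _LOWER, rng.randint(0, 3)),
        sample_number=rng.choice([None, rng.randint(1, 20)]),
    )


def _token(rng: random.Random) -> str:
    # a generic dotted-field token; never purely numeric (numeric tokens are
    # version/minor slots in the grammar)
    tok = _letters(rng, _TOKEN_CHARS, rng.randint(1, 8))
    if tok.isdigit():
        tok += rng.choice(_LOWER)
    return tok


def _group_token(rng: random.Random) -> str:
    # the group slot must not look like a version field ("v3", "12")
    tok = _token(rng)
    if re.fullmatch(r"v?[0-9]+", tok):
        tok = "G" + tok
    return tok


def random_assembly_name(rng: random.Random) -> AssemblyName:
    return AssemblyName(
        tolid=random_tolid(rng),
        sample_name=_token(rng),
        group=rng.choice([None, _group_token(rng)]) if rng.random() < 0.7 else None,
        version_major=rng.randint(1, 12),
        version_minor=rng.choice([None, rng.randint(0, 9)]),
        has_v_prefix=rng.random() < 0.3,
        extras=tuple(_token(rng) for _ in range(rng.randint(0, 2))),
    )


def random_region(rng: random.Random) -> SeqRegion:
    if rng.random() < 0.8:
        number = rng.randint(1, 99)
        pad = max(rng.choice([1, 2, 3]), len(str(number)))
        return SeqRegion(
            kind="chromosome",
            number=number,
            pad_width=pad,
            subgenome=rng.choice([None, rng.choice(_UPPER)]),
            haplotype=rng.choice([None, rng.choice(["Hap", "hap", "HAP"]) + str(rng.randint(1, 4))]),
        )
    return SeqRegion(kind="scaffold", number="scaffold_" + str(rng.randint(1, 500)), pad_width=1)


def random_gene_model_id(rng: random.Random) -> GeneModelID:
    width = rng.choice([2, 4, 6, 6, 6])
    number = rng.randrange(0, 10**width)
    return GeneModelID(
        assembly=random_assembly_name(rng),
        annotation=AnnotationVersion(rng.randint(1, 9)),
        region=random_region(rng),
        entity_type=rng.choice(["g", "g", "g", "p", "t", "pan"]),
        entity_number=number,
        entity_prefix=rng.choice([None, None, rng.choice("xyz")]),
        entity_pad_width=width,
        transcript_number=rng.choice([None, None, rng.randint(1, 15)]),
    )
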