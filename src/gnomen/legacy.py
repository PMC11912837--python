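"""Detection and lossless decomposition of legacy community identifier schemes.

Each crop community historically invented its own gene-model and assembly
naming pattern (wheat ``TraesCS3D02G273600``, maize ``Zm00001eb000050``,
brassica ``C01p010030.1_BnaDAR`` ...).  Every scheme here is a regex with
named groups plus a literal template, so a parsed :class:`LegacyRecord`
re-assembles byte-identically to the raw input — the decomposition is
lossless by construction.  Detection walks the registry in a fixed,
most-specific-first order, so it is deterministic; anything unmatched is
reported as ``unknown`` rather than guessed at.

Punctuation attached to optional pieces (a ``.1`` transcript suffix, a
``_TAIR12`` annotation tag) is captured inside the group itself, keeping the
templates pure concatenation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .identifiers import IdentifierError

__all__ = [
    "LegacyRecord",
    "SchemeDef",
    "SchemeRegistry",
    "default_registry",
    "detect_scheme",
    "parse_legacy",
    "parse_legacy_assembly",
    "records_to_tsv",
]

# LegacyRecord attributes that regex group names map onto directly;
# any other group name lands in the record's `extra` dict.
_RECORD_FIELDS = frozenset(
    {
        "species_token",
        "accession",
        "subgenome",
        "chromosome",
        "haplotype",
        "entity_letter",
        "entity_number",
        "assembly_version_token",
        "annotation_version_token",
        "transcript_token",
        "group",
        "taxon",
    }
)

TSV_COLUMNS = (
    "raw",
    "scheme",
    "species_token",
    "accession",
    "subgenome",
    "chromosome",
    "haplotype",
    "entity_letter",
    "entity_number",
    "assembly_version_token",
    "annotation_version_token",
    "transcript_token",
    "group",
    "taxon",
)


@dataclass(frozen=True)
class LegacyRecord:
    """Fields extracted from one legacy identifier under one scheme.

    ``entity_number`` keeps its zero padding as a string so conversion can
    re-pad explicitly.  Scheme-specific leftovers (barley's constant genome
    letter, TAIR's assembly short ID, an assembly method tag) live in
    ``extra``.
    """

    scheme: str
    raw: str
    species_token: Optional[str] = None
    accession: Optional[str] = None
    subgenome: Optional[str] = None
    chromosome: Optional[str] = None
    haplotype: Optional[str] = None
    entity_letter: Optional[str] = None
    entity_number: Optional[str] = None
    assembly_version_token: Optional[str] = None
    annotation_version_token: Optional[str] = None
    transcript_token: Optional[str] = None
    group: Optional[str] = None
    taxon: Optional[str] = None
    extra: dict = field(default_factory=dict)

    # alias matching the common field wording
    @property
    def accession_or_cultivar(self) -> Optional[str]:
        return self.accession

    def groups(self) -> dict:
        d = {k: getattr(self, k) for k in _RECORD_FIELDS if getattr(self, k) is not None}
        d.update(self.extra)
        return d

    def assemble(self, registry: Optional["SchemeRegistry"] = None) -> str:
        """Reconstruct the raw identifier from the fields via the scheme template."""
        scheme = (registry or default_registry()).get(self.scheme)
        values = {k: "" for k in scheme.group_names}
        values.update({k: v for k, v in self.groups().items() if k in values})
        return scheme.template.format(**values)


@dataclass(frozen=True)
class SchemeDef:
    name: str
    kind: str  # "gene" | "assembly"
    pattern: re.Pattern
    template: str
    description: str = ""

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.pattern.groupindex)

    def parse(self, s: str) -> LegacyRecord:
        m = self.pattern.fullmatch(s)
        if not m:
            raise IdentifierError(
                f"{s!r} does not match scheme {self.name!r} ({self.description or self.template})",
                code="SCHEME_MISMATCH",
            )
        named = {}
        extra = {}
        for key, value in m.groupdict().items():
            if value is None:
                continue
            if key in _RECORD_FIELDS:
                named[key] = value
            else:
                extra[key] = value
        return LegacyRecord(scheme=self.name, raw=s, extra=extra, **named)


class SchemeRegistry:
    """Ordered collection of scheme definitions; order resolves ambiguity."""

    def __init__(self, schemes: Sequence[SchemeDef]):
        self.schemes = tuple(schemes)
        self._by_name = {sc.name: sc for sc in schemes}
        if len(self._by_name) != len(self.schemes):
            raise ValueError("duplicate scheme names in registry")

    def __iter__(self):
        return iter(self.schemes)

    def get(self, name: str) -> SchemeDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise IdentifierError(f"no scheme named {name!r} in the registry", code="SCHEME") from None

    def detect(self, s: str, kind: Optional[str] = None) -> str:
        for sc in self.schemes:
            if kind is not None and sc.kind != kind:
                continue
            if sc.pattern.fullmatch(s):
                return sc.name
        return "unknown"


def _scheme(name: str, kind: str, pattern: str, template: str, description: str = "") -> SchemeDef:
    return SchemeDef(name=name, kind=kind, pattern=re.compile(pattern), template=template, description=description)


_DEFAULT_SCHEMES: tuple[SchemeDef, ...] = (
    # ---- gene-model schemes -------------------------------------------------
    _scheme(
        "wheat_traes",
        "gene",
        r"(?P<species_token>Traes)(?P<accession>[A-Z]{2})(?P<chromosome>\d)(?P<subgenome>[A-Z])"
        r"(?P<annotation_version_token>\d{2})(?P<entity_letter>[A-Z])(?P<entity_number>\d+)"
        r"(?P<transcript_token>\.\d+)?",
        "{species_token}{accession}{chromosome}{subgenome}{annotation_version_token}{entity_letter}{entity_number}{transcript_token}",
        "Traes<accession><chr><subgenome><annot><ENTITY><number>",
    ),
    _scheme(
        "brassica_bna",
        "gene",
        r"(?P<subgenome>[AC])(?P<chromosome>\d{2})(?P<entity_letter>[a-z])(?P<entity_number>\d+)"
        r"(?P<annotation_version_token>\.\d+)?_Bna(?P<accession>[A-Z][A-Za-z0-9]*)",
        "{subgenome}{chromosome}{entity_letter}{entity_number}{annotation_version_token}_Bna{accession}",
        "<subgenome><chr><entity><number>[.annot]_Bna<accession>",
    ),
    _scheme(
        "barley_horvu_morex",
        "gene",
        r"(?P<species_token>HORVU)\.(?P<accession>[A-Z]+)\.(?P<assembly_version_token>r\d+)\."
        r"(?P<chromosome>\d+)(?P<genome_letter>H)(?P<entity_letter>G)(?P<entity_number>\d+)"
        r"(?P<transcript_token>\.\d+)?",
        "{species_token}.{accession}.{assembly_version_token}.{chromosome}{genome_letter}{entity_letter}{entity_number}{transcript_token}",
        "HORVU.<accession>.r<ver>.<chr>HG<number>",
    ),
    _scheme(
        "barley_horvu_barke",
        "gene",
        r"(?P<species_token>Horvu)_(?P<accession>[A-Z]+)_(?P<chromosome>\d)(?P<genome_letter>H)"
        r"(?P<annotation_version_token>\d{2})(?P<entity_letter>G)(?P<entity_number>\d+)"
        r"(?P<transcript_token>\.\d+)?",
        "{species_token}_{accession}_{chromosome}{genome_letter}{annotation_version_token}{entity_letter}{entity_number}{transcript_token}",
        "Horvu_<accession>_<chr>H<annot>G<number>[.transcript]",
    ),
    _scheme(
        "soybean_glyma",
        "gene",
        r"(?P<species_token>Glyma)\.(?P<chromosome>\d{2})(?P<entity_letter>[a-z])(?P<entity_number>\d+)"
        r"\.(?P<accession>[A-Za-z][A-Za-z0-9]*)\.(?P<assembly_version_token>a\d+)\.(?P<annotation_version_token>v\d+)",
        "{species_token}.{chromosome}{entity_letter}{entity_number}.{accession}.{assembly_version_token}.{annotation_version_token}",
        "Glyma.<chr><entity><number>.<accession>.a<asm>.v<annot>",
    ),
    _scheme(
        "grape_vitvi",
        "gene",
        r"(?P<species_token>Vitvi)(?P<chromosome>\d{2})(?P<entity_letter>[a-z])(?P<entity_number>\d+)"
        r"(?P<transcript_token>\.\d+)?",
        "{species_token}{chromosome}{entity_letter}{entity_number}{transcript_token}",
        "Vitvi<chr><entity><number>",
    ),
    _scheme(
        "maize_zm",
        "gene",
        r"(?P<species_token>Zm)(?P<accession>\d{5})(?P<assembly_version_token>[a-z])"
        r"(?P<annotation_version_token>[a-z])(?P<entity_number>\d{6})(?P<transcript_token>_T\d+)?",
        "{species_token}{accession}{assembly_version_token}{annotation_version_token}{entity_number}{transcript_token}",
        "Zm<accession 5d><asm letter><annot letter><number 6d>",
    ),
    _scheme(
        "sorghum_sobic",
        "gene",
        r"(?P<species_token>SORBI_3|Sobic\.)(?P<chromosome>\d{3})(?P<entity_letter>G)(?P<entity_number>\d+)"
        r"(?P<transcript_token>\.\d+)?",
        "{species_token}{chromosome}{entity_letter}{entity_number}{transcript_token}",
        "(SORBI_3|Sobic.)<chr 3d>G<number>",
    ),
    _scheme(
        "gdr_maldo",
        "gene",
        r"(?P<species_token>[A-Z][a-z]{4})\.(?P<accession>[a-z0-9]+)\.(?P<assembly_version_token>v\d+)"
        r"(?P<annotation_version_token>a\d+)\.ch(?P<chromosome>\d+)(?P<haplotype>[A-Z])"
        r"\.(?P<entity_letter>[a-z])(?P<entity_number>\d+)(?P<transcript_token>\.t\d+)?",
        "{species_token}.{accession}.{assembly_version_token}{annotation_version_token}.ch{chromosome}{haplotype}.{entity_letter}{entity_number}{transcript_token}",
        "<Species5>.<cultivar>.v<asm>a<annot>.ch<chr><haplome>.<entity><number>[.t<n>]",
    ),
    _scheme(
        "honeycrisp_hap",
        "gene",
        r"(?P<accession>[A-Za-z][A-Za-z0-9]*)_(?P<haplotype>HAP\d+)_(?P<assembly_version_token>v\d+(?:\.\d+)?)"
        r"\.(?P<entity_number>\d+)",
        "{accession}_{haplotype}_{assembly_version_token}.{entity_number}",
        "<cultivar>_HAP<n>_v<ver>.<number>",
    ),
    _scheme(
        "tair_agi",
        "gene",
        r"(?P<species_token>At)(?P<chromosome>[1-5CM])(?P<entity_letter>g)(?P<entity_number>\d+)"
        r"(?P<transcript_token>\.\d+)?(?P<annotation_version_token>_TAIR\d+)?",
        "{species_token}{chromosome}{entity_letter}{entity_number}{transcript_token}{annotation_version_token}",
        "At<chr>g<number>[.transcript][_TAIR<annot>]",
    ),
    _scheme(
        "fragaria_fv",
        "gene",
        r"(?P<species_token>Fv)\.(?P<chromosome>\d{2})(?P<entity_letter>g)(?P<entity_number>\d+)"
        r"(?P<transcript_token>\.t\d+)?",
        "{species_token}.{chromosome}{entity_letter}{entity_number}{transcript_token}",
        "Fv.<chr>g<number>",
    ),
    # ---- assembly schemes ---------------------------------------------------
    _scheme(
        "tair_assembly",
        "assembly",
        r"(?P<species_token>[A-Z][a-z])(?P<taxon>\d+)\.(?P<accession>[A-Za-z0-9-]+)\."
        r"(?P<assembly_id>[A-Za-z0-9-]+)\.(?P<assembly_version_token>v\d+)",
        "{species_token}{taxon}.{accession}.{assembly_id}.{assembly_version_token}",
        "<GsTaxon>.<variety>.<ID>.v<version>",
    ),
    _scheme(
        "maize_zm_assembly",
        "assembly",
        r"(?P<species_token>Zm)-(?P<accession>[A-Za-z0-9]+)-REFERENCE-(?P<group>[A-Za-z0-9]+)-"
        r"(?P<assembly_version_token>\d+\.\d+)",
        "{species_token}-{accession}-REFERENCE-{group}-{assembly_version_token}",
        "Zm-<accession>-REFERENCE-<group>-<ver>",
    ),
    _scheme(
        "gdr_maldo_assembly",
        "assembly",
        r"(?P<species_token>[A-Z][a-z]{4})\.(?P<accession>[a-z0-9]+)\.(?P<assembly_version_token>v\d+)"
        r"\.ch(?P<chromosome>\d+)(?P<haplotype>[A-Z])",
        "{species_token}.{accession}.{assembly_version_token}.ch{chromosome}{haplotype}",
        "<Species5>.<cultivar>.v<ver>.ch<chr><haplome>",
    ),
    _scheme(
        "morex_assembly",
        "assembly",
        r"(?P<accession>[A-Za-z]+?)(?P<assembly_version_token>V\d+)_pseudomolecules_assembly",
        "{accession}{assembly_version_token}_pseudomolecules_assembly",
        "<Accession>V<ver>_pseudomolecules_assembly",
    ),
    _scheme(
        "ensembl_ast_assembly",
        "assembly",
        r"AST_(?P<accession>[A-Z0-9]+)_(?P<assembly_version_token>v\d+)",
        "AST_{accession}_{assembly_version_token}",
        "AST_<project accession>_v<ver>",
    ),
    _scheme(
        "culicoides_assembly",
        "assembly",
        r"(?P<species_token>[A-Z]_[a-z]+)_(?P<assembly_version_token>v\d+)_(?P<method>[a-z]+)",
        "{species_token}_{assembly_version_token}_{method}",
        "<G_species>_v<ver>_<method>",
    ),
    _scheme(
        "soy_wm82_assembly",
        "assembly",
        r"(?P<accession>Wm\d+)\.(?P<assembly_version_token>a\d+)\.(?P<annotation_version_token>v\d+)",
        "{accession}.{assembly_version_token}.{annotation_version_token}",
        "Wm<n>.a<asm>.v<annot>",
    ),
    _scheme(
        "vgp_style",
        "assembly",
        r"(?P<species_token>[a-z]{1,2}[A-Z][a-z]{0,2}[A-Z][a-z]{0,3}\d*)\."
        r"(?P<assembly_version_token>\d+(?:\.\d+)?)",
        "{species_token}.{assembly_version_token}",
        "<ToLID>.<version>",
    ),
)


_DEFAULT_REGISTRY = SchemeRegistry(_DEFAULT_SCHEMES)


def default_registry() -> SchemeRegistry:
    return _DEFAULT_REGISTRY


def detect_scheme(s: str, registry: Optional[SchemeRegistry] = None, kind: Optional[str] = None) -> str:
    """Name of the first registry scheme fully matching ``s``, else 'unknown'."""
    return (registry or _DEFAULT_REGISTRY).detect(s, kind=kind)


def parse_legacy(s: str, scheme: Optional[str] = None, registry: Optional[SchemeRegistry] = None) -> LegacyRecord:
    """Decompose a legacy gene-model identifier (auto-detected unless named)."""
    return _parse(s, scheme, registry, kind="gene")


def parse_legacy_assembly(s: str, scheme: Optional[str] = None, registry: Optional[SchemeRegistry] = None) -> LegacyRecord:
    """Decompose a legacy assembly identifier (auto-detected unless named)."""
    return _parse(s, scheme, registry, kind="assembly")


def _parse(s: str, scheme: Optional[str], registry: Optional[SchemeRegistry], kind: str) -> LegacyRecord:
    reg = registry or _DEFAULT_REGISTRY
    if scheme is None:
        scheme = reg.detect(s, kind=kind)
        if scheme == "unknown":
            raise IdentifierError(f"{s!r} matches no known {kind} scheme", code="UNKNOWN_SCHEME")
    return reg.get(scheme).parse(s)


def records_to_tsv(records: Iterable[LegacyRecord]) -> str:
    """Batch output: one TSV row per record, one column per field plus scheme."""
    lines = ["\t".join(TSV_COLUMNS)]
    for rec in records:
        lines.append("\t".join(getattr(rec, col) or "" for col in TSV_COLUMNS))
    return "\n".join(lines) + "\n"
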