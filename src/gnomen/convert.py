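"""Map legacy identifiers plus species metadata onto the standardized scheme.

A legacy gene-model ID rarely carries everything the new scheme needs (the
grape community's ``Vitvi18g12230`` says nothing about which cultivar was
sequenced), so conversion combines a parsed :class:`~gnomen.legacy.LegacyRecord`
with a per-species :class:`ConversionConfig`.  The entity number's integer
value is always preserved — only its zero padding changes — and chromosome
and subgenome letters carry over verbatim (re-padded).

Version handling follows the attested community tokens: ``a2`` -> assembly 2,
``r3`` -> 3, ``v1.0`` -> 1.  Annotation versions are never inferred from the
legacy string (wheat's ``02`` infix and soybean's ``v1`` are annotation-side
bookkeeping of the *old* scheme); the new annotation ordinal is configuration,
default 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .identifiers import (
    AnnotationVersion,
    AssemblyName,
    GeneModelID,
    IdentifierError,
    SeqRegion,
    ToLID,
    serialize_assembly_name,
    serialize_gene_model_id,
)
from .legacy import LegacyRecord, SchemeRegistry, default_registry
from .tolid import CladePrefixTable, TaxonDescriptor, build_tolid

__all__ = [
    "ConversionConfig",
    "RowResult",
    "infer_assembly_version",
    "convert_assembly",
    "convert_gene_model",
    "convert_table",
    "rows_to_tsv",
]

# legacy entity letters -> new-scheme entity types
ENTITY_MAP = {
    "g": "g",
    "G": "g",
    "p": "p",
    "P": "p",
    "t": "t",
    "T": "t",
    "pan": "pan",
}

_VERSION_TOKEN_RE = re.compile(r"^[varVAR]?(\d+)(?:\.(\d+))?$")
_HAP_RE = re.compile(r"^(?:[Hh]ap|HAP)0*(\d+)$")


@dataclass
class ConversionConfig:
    """Per-species settings for legacy-to-new conversion.

    Supply either a ready ``tolid`` or a ``taxon`` descriptor (built through
    the offline clade table).  ``supplemental`` provides fields absent from
    the legacy scheme itself — most commonly a chromosome for schemes that
    never encoded one; such user-supplied chromosome strings are used in
    their given display form (not re-padded).
    """

    tolid: Optional[ToLID] = None
    taxon: Optional[TaxonDescriptor] = None
    clade_table: Optional[CladePrefixTable] = None
    sample_name: Optional[str] = None
    group: Optional[str] = None
    assembly_version: Optional[int] = None
    assembly_version_minor: int = 0
    annotation_version: int = 1
    chromosome_pad_width: int = 2
    entity_pad_width: int = 6
    supplemental: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chromosome_pad_width < 1 or self.entity_pad_width < 1:
            raise IdentifierError("pad widths must be >= 1", code="CONFIG")
        if self.annotation_version < 1:
            raise IdentifierError("annotation version must be >= 1", code="CONFIG")
        if self.assembly_version is not None and self.assembly_version < 1:
            raise IdentifierError("assembly major version must be >= 1", code="CONFIG")

    def resolve_tolid(self) -> ToLID:
        if self.tolid is not None:
            return self.tolid
        if self.taxon is not None:
            return build_tolid(self.taxon, table=self.clade_table)
        raise IdentifierError(
            "conversion requires a ToLID: set `tolid` directly or supply a taxon descriptor "
            "with a resolvable clade prefix",
            code="TOLID_REQUIRED",
        )


def infer_assembly_version(token: Optional[str]) -> Optional[int]:
    """Major assembly version from a legacy version token.

    ``a2`` -> 2, ``r3`` -> 3, ``v1.0`` -> 1, ``5.0`` -> 5, ``V3`` -> 3;
    anything else (including the purely annotation-side tokens) -> None.
    """
    if not token:
        return None
    m = _VERSION_TOKEN_RE.fullmatch(token)
    if not m:
        return None
    major = int(m.group(1))
    return major if major >= 1 else None


def _resolved_version(rec: LegacyRecord, cfg: ConversionConfig) -> int:
    if cfg.assembly_version is not None:
        return cfg.assembly_version
    return infer_assembly_version(rec.assembly_version_token) or 1


def _sample_name(rec: LegacyRecord, cfg: ConversionConfig) -> str:
    sample = cfg.sample_name or rec.accession
    if not sample:
        raise IdentifierError(
            f"no sample/variety name available for {rec.raw!r}: the {rec.scheme} scheme does not "
            "encode one, so set `sample_name` in the conversion config",
            code="SAMPLE_REQUIRED",
        )
    return sample


def convert_assembly(rec: LegacyRecord, cfg: ConversionConfig) -> AssemblyName:
    """New-scheme assembly name for a legacy record (converted-table style).

    Emits ``<ToLID>.<sample>.<major>.<minor>`` with minor defaulting to 0; a
    haplotype token found in the legacy ID is appended verbatim as an extra
    field.  The sequencing group is included only when configured.
    """
    extras = []
    if rec.haplotype:
        extras.append(rec.haplotype)
    return AssemblyName(
        tolid=cfg.resolve_tolid(),
        sample_name=_sample_name(rec, cfg),
        group=cfg.group,
        version_major=_resolved_version(rec, cfg),
        version_minor=cfg.assembly_version_minor,
        extras=tuple(extras),
    )


def _region_from(rec: LegacyRecord, cfg: ConversionConfig) -> SeqRegion:
    subgenome = rec.subgenome.upper() if rec.subgenome else None
    haplotype = None
    if rec.haplotype:
        m = _HAP_RE.fullmatch(rec.haplotype)
        if m:
            haplotype = f"Hap{m.group(1)}"
        elif re.fullmatch(r"[A-Z]", rec.haplotype) and subgenome is None:
            # single-letter haplome designation (e.g. GDR's "ch10A") rides in the letter slot
            subgenome = rec.haplotype
        else:
            raise IdentifierError(f"cannot interpret haplotype token {rec.haplotype!r}", code="REGION")
    chrom = rec.chromosome
    if chrom is not None and chrom.isdigit():
        pad = max(cfg.chromosome_pad_width, len(str(int(chrom))))
        return SeqRegion(kind="chromosome", number=int(chrom), pad_width=pad, subgenome=subgenome, haplotype=haplotype)
    if chrom is None:
        supp = cfg.supplemental.get("chromosome")
        if supp is None:
            raise IdentifierError(
                f"the {rec.scheme} scheme carries no chromosome; supply one via the config's "
                "supplemental fields",
                code="CHR_REQUIRED",
            )
        supp = str(supp)
        if supp.isdigit():
            # user-supplied display form is trusted as-is
            return SeqRegion(kind="chromosome", number=int(supp), pad_width=len(supp), subgenome=subgenome, haplotype=haplotype)
        chrom = supp
    return SeqRegion(kind="scaffold", number=chrom, pad_width=1, subgenome=subgenome, haplotype=haplotype)


def convert_gene_model(rec: LegacyRecord, cfg: ConversionConfig) -> GeneModelID:
    """New-scheme gene-model ID for a legacy record.

    The legacy entity letter is lowercased into {g, p, t, pan} (records with
    no entity letter are gene models, ``g``); the entity number is re-padded
    to ``entity_pad_width``.  Legacy transcript suffixes are dropped: the new
    ID names the gene model itself.
    """
    if rec.entity_number is None:
        raise IdentifierError(f"{rec.raw!r} carries no entity number; cannot form a gene-model ID", code="NO_NUMBER")
    letter = rec.entity_letter
    if letter is None:
        etype = "g"
    else:
        try:
            etype = ENTITY_MAP[letter]
        except KeyError:
            raise IdentifierError(
                f"legacy entity letter {letter!r} has no mapping into {{g, p, t, pan}}",
                code="ENTITY",
            ) from None
    assembly = AssemblyName(
        tolid=cfg.resolve_tolid(),
        sample_name=_sample_name(rec, cfg),
        group=cfg.group,
        version_major=_resolved_version(rec, cfg),
        version_minor=None,  # gene-model IDs carry the major version only
    )
    return GeneModelID(
        assembly=assembly,
        annotation=AnnotationVersion(cfg.annotation_version),
        region=_region_from(rec, cfg),
        entity_type=etype,
        entity_number=int(rec.entity_number),
        entity_pad_width=cfg.entity_pad_width,
    )


@dataclass(frozen=True)
class RowResult:
    raw: str
    scheme: str
    new_assembly: str = ""
    new_gene_id: str = ""
    error: str = ""


def convert_table(
    rows: Iterable[str],
    configs: Mapping[str, ConversionConfig],
    registry: Optional[SchemeRegistry] = None,
    dialect: str = "canonical",
) -> list[RowResult]:
    """Convert a batch of legacy identifiers; one output row per input.

    ``configs`` maps scheme names to their species config.  Unknown schemes
    are passed through flagged ``unknown``; per-row failures land in the
    error column rather than aborting the batch.  Row order follows input
    order, so identical inputs and configs give byte-identical TSV output.
    """
    reg = registry or default_registry()
    out: list[RowResult] = []
    for raw in rows:
        raw = raw.strip()
        if not raw:
            continue
        scheme = reg.detect(raw)
        if scheme == "unknown":
            out.append(RowResult(raw=raw, scheme="unknown"))
            continue
        cfg = configs.get(scheme)
        if cfg is None:
            out.append(RowResult(raw=raw, scheme=scheme, error=f"NO_CONFIG: no conversion config for scheme {scheme}"))
            continue
        try:
            rec = reg.get(scheme).parse(raw)
            assembly = serialize_assembly_name(convert_assembly(rec, cfg))
            if reg.get(scheme).kind == "gene":
                gene = serialize_gene_model_id(convert_gene_model(rec, cfg), dialect=dialect)
            else:
                gene = ""
            out.append(RowResult(raw=raw, scheme=scheme, new_assembly=assembly, new_gene_id=gene))
        except IdentifierError as e:
            out.append(RowResult(raw=raw, scheme=scheme, error=f"{e.code}: {e}"))
    return out


def rows_to_tsv(rows: Sequence[RowResult]) -> str:
    lines = ["raw\tscheme\tnew_assembly_id\tnew_gene_model_id\terror"]
    for r in rows:
        lines.append(f"{r.raw}\t{r.scheme}\t{r.new_assembly}\t{r.new_gene_id}\t{r.error}")
    return "\n".join(lines) + "\n"
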