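"""Canonical grammar for standardized genome-assembly and gene-model identifiers.

The scheme encodes, in dotted fields, everything needed to trace a gene model
back to its annotation and source assembly:

    assembly name   <ToLID>.<variety>[.<group>].<major>[.<minor>][.<extras>...]
    gene-model ID   <ToLID>.<variety>[.<group>].<major>.<annotation>.<region><entity><number>[.<transcript>]

where the region is a zero-padded chromosome number optionally followed by a
subgenome letter (polyploids, e.g. wheat "03D") and/or a haplotype tag
(phased assemblies, e.g. "3Hap1"), or a scaffold token for unplaced sequence.

Period is the sole field separator; hyphen and underscore are legal inside
tokens.  Everything here is pure string/structure manipulation: parsing is
exact, serialization is canonical, and ``parse(serialize(x)) == x`` holds at
field level for every valid value.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "IdentifierError",
    "ToLID",
    "AssemblyName",
    "AnnotationVersion",
    "SeqRegion",
    "GeneModelID",
    "Issue",
    "ValidationReport",
    "parse_assembly_name",
    "serialize_assembly_name",
    "parse_gene_model_id",
    "serialize_gene_model_id",
    "validate_name",
    "report_to_tsv",
    "report_to_jsonl",
    "sanitize_token",
]

# Character set legal inside a single dotted field.
TOKEN_RE = re.compile(r"^[A-Za-z0-9_-]+$")
TOLID_RE = re.compile(r"^([a-z]{1,2})([A-Z][a-z]{0,2})([A-Z][a-z]{0,3})([0-9]*)$")
VERSION_RE = re.compile(r"^(v?)([0-9]+)$")
MINOR_RE = re.compile(r"^[0-9]+$")
CHROM_RE = re.compile(r"^([0-9]+)([A-Z])?((?:[Hh]ap|HAP)[0-9]+)?$")
HAPLOTYPE_RE = re.compile(r"^(?:[Hh]ap|HAP)[0-9]+$")
ENTITY_TYPES = ("g", "p", "t", "pan")
ENTITY_RE = re.compile(r"^([A-Za-z]?)(pan|g|p|t)([0-9]+)$")

DEFAULT_MAX_LENGTH = 100
DEFAULT_ENTITY_PAD = 6
DEFAULT_CHROM_PAD = 2


class IdentifierError(ValueError):
    """Raised when an identifier cannot be parsed or serialized.

    ``code`` is a short machine-readable token (e.g. ``EMPTY_FIELD``) and
    ``span`` the offending character range in the input, when known.
    """

    def __init__(self, message: str, code: str = "PARSE", span: Optional[tuple[int, int]] = None):
        super().__init__(message)
        self.code = code
        self.span = span


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToLID:
    """Tree-of-Life species/sample code, e.g. ``drMalDome`` or ``idCulSono2``.

    One lowercase letter for the high-level taxonomic rank, one for the clade
    (vertebrates use the rank letter only), 1 upper + up to 2 lowercase for
    the genus, 1 upper + up to 3 lowercase for the species (up to 2 for
    vertebrates), and an optional sequential sample number starting at 1.
    """

    rank_letter: str
    genus_code: str
    species_code: str
    clade_letter: Optional[str] = None
    sample_number: Optional[int] = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[a-z]", self.rank_letter or ""):
            raise IdentifierError(f"ToLID rank letter must be one lowercase ascii letter, got {self.rank_letter!r}", code="TOLID")
        if self.clade_letter is not None and not re.fullmatch(r"[a-z]", self.clade_letter):
            raise IdentifierError(f"ToLID clade letter must be one lowercase ascii letter, got {self.clade_letter!r}", code="TOLID")
        if not re.fullmatch(r"[A-Z][a-z]{0,2}", self.genus_code):
            raise IdentifierError(f"genus code must be 1 uppercase + up to 2 lowercase letters, got {self.genus_code!r}", code="TOLID")
        if not re.fullmatch(r"[A-Z][a-z]{0,3}", self.species_code):
            raise IdentifierError(f"species code must be 1 uppercase + up to 3 lowercase letters, got {self.species_code!r}", code="TOLID")
        if self.sample_number is not None and self.sample_number < 1:
            raise IdentifierError("sample number must be a positive integer", code="TOLID")

    @classmethod
    def parse(cls, s: str) -> "ToLID":
        m = TOLID_RE.fullmatch(s)
        if not m:
            raise IdentifierError(f"malformed ToLID {s!r} (expected e.g. 'drMalDome')", code="TOLID", span=(0, len(s)))
        prefix, genus, species, sample = m.groups()
        if sample and sample[0] == "0":
            raise IdentifierError(f"ToLID sample number may not have leading zeros: {s!r}", code="TOLID")
        return cls(
            rank_letter=prefix[0],
            clade_letter=prefix[1] if len(prefix) == 2 else None,
            genus_code=genus,
            species_code=species,
            sample_number=int(sample) if sample else None,
        )

    def __str__(self) -> str:
        return "{}{}{}{}{}".format(
            self.rank_letter,
            self.clade_letter or "",
            self.genus_code,
            self.species_code,
            self.sample_number if self.sample_number is not None else "",
        )


def _check_token(tok: str, what: str) -> str:
    if "." in tok or re.search(r"\s", tok):
        raise IdentifierError(f"{what} {tok!r} may not contain periods or whitespace", code="BAD_TOKEN")
    if not TOKEN_RE.fullmatch(tok):
        raise IdentifierError(f"{what} {tok!r} contains characters outside [A-Za-z0-9_-]", code="CHARSET")
    return tok


@dataclass(frozen=True)
class AssemblyName:
    """A standardized assembly name: species, individual, project group, version.

    ``extras`` carries the optional trailing fields in order — a haplotype tag
    for phased assemblies, ``organelles``, or a legacy name appended to ease
    transition.
    """

    tolid: ToLID
    sample_name: str
    version_major: int
    group: Optional[str] = None
    version_minor: Optional[int] = None
    has_v_prefix: bool = False
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_token(self.sample_name, "sample name")
        if self.group is not None:
            _check_token(self.group, "sequencing group")
        if self.version_major < 1:
            raise IdentifierError("assembly major version must be >= 1", code="VERSION")
        if self.version_minor is not None and self.version_minor < 0:
            raise IdentifierError("assembly minor version must be >= 0", code="VERSION")
        for tok in self.extras:
            _check_token(tok, "extra field")

    def fields(self) -> tuple[str, ...]:
        """The dotted fields of the canonical serialization, in order."""
        out = [str(self.tolid), self.sample_name]
        if self.group is not None:
            out.append(self.group)
        out.append(("v" if self.has_v_prefix else "") + str(self.version_major))
        if self.version_minor is not None:
            out.append(str(self.version_minor))
        out.extend(self.extras)
        return tuple(out)

    def __str__(self) -> str:
        return serialize_assembly_name(self)


@dataclass(frozen=True)
class AnnotationVersion:
    """Ordinal of an annotation dataset computed on one assembly (>= 1)."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 1:
            raise IdentifierError("annotation version must be >= 1", code="VERSION")

    def __str__(self) -> str:
        return str(self.value)


@dataclass(frozen=True)
class SeqRegion:
    """Chromosome (or scaffold) slot of a gene-model identifier.

    Chromosomes serialize as zero-padded digits plus optional subgenome letter
    plus optional haplotype tag, with no internal separators ("01C", "3Hap1").
    Scaffolds carry their sanitized token verbatim.
    """

    kind: str  # "chromosome" | "scaffold"
    number: object  # int for chromosomes, str token for scaffolds
    pad_width: int = DEFAULT_CHROM_PAD
    subgenome: Optional[str] = None
    haplotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("chromosome", "scaffold"):
            raise IdentifierError(f"unknown region kind {self.kind!r}", code="REGION")
        if self.pad_width < 1:
            raise IdentifierError("pad width must be >= 1", code="REGION")
        if self.kind == "chromosome":
            if not isinstance(self.number, int) or self.number < 1:
                raise IdentifierError("chromosome number must be a positive integer", code="REGION")
        else:
            _check_token(str(self.number), "scaffold token")
        if self.subgenome is not None and not re.fullmatch(r"[A-Z]", self.subgenome):
            raise IdentifierError(f"subgenome must be a single uppercase letter, got {self.subgenome!r}", code="REGION")
        if self.haplotype is not None and not HAPLOTYPE_RE.fullmatch(self.haplotype):
            raise IdentifierError(f"haplotype must match Hap<digits>, got {self.haplotype!r}", code="REGION")

    @classmethod
    def parse(cls, token: str) -> "SeqRegion":
        m = CHROM_RE.fullmatch(token)
        if m:
            digits, sub, hap = m.groups()
            return cls(kind="chromosome", number=int(digits), pad_width=len(digits), subgenome=sub, haplotype=hap)
        _check_token(token, "scaffold token")
        return cls(kind="scaffold", number=token, pad_width=1)

    def __str__(self) -> str:
        if self.kind == "chromosome":
            body = str(self.number).zfill(self.pad_width)
        else:
            body = str(self.number)
        return body + (self.subgenome or "") + (self.haplotype or "")


@dataclass(frozen=True)
class GeneModelID:
    """A gene-model/transcript identifier: assembly, annotation, region, entity.

    Entity types: ``g`` gene, ``p`` protein, ``t`` transcript, ``pan``
    pan-gene; an optional single character may precede the type letter.  The
    entity number is zero-padded to ``entity_pad_width`` (6 digits suffice for
    all gene models of an assembly); a trailing ordinal identifies one of the
    gene's transcripts, with no assumption about which one is canonical.
    """

    assembly: AssemblyName
    annotation: AnnotationVersion
    region: SeqRegion
    entity_type: str
    entity_number: int
    entity_prefix: Optional[str] = None
    entity_pad_width: int = DEFAULT_ENTITY_PAD
    transcript_number: Optional[int] = None

    FIELD_SLOTS = ("assembly", "annotation", "region", "entity_type", "entity_number", "transcript_number")

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise IdentifierError(
                f"unknown entity type {self.entity_type!r}; allowed: {', '.join(ENTITY_TYPES)}",
                code="ENTITY",
            )
        if self.entity_prefix is not None and not re.fullmatch(r"[A-Za-z]", self.entity_prefix):
            raise IdentifierError("entity prefix must be a single letter", code="ENTITY")
        if self.entity_number < 0:
            raise IdentifierError("entity number must be non-negative", code="ENTITY")
        if self.entity_pad_width < 1:
            raise IdentifierError("entity pad width must be >= 1", code="ENTITY")
        if len(str(self.entity_number)) > self.entity_pad_width:
            raise IdentifierError(
                f"entity number {self.entity_number} overflows pad width {self.entity_pad_width}",
                code="OVERFLOW",
            )
        if self.transcript_number is not None and self.transcript_number < 1:
            raise IdentifierError("transcript number must be >= 1", code="TRANSCRIPT")

    def entity_token(self) -> str:
        return (self.entity_prefix or "") + self.entity_type + str(self.entity_number).zfill(self.entity_pad_width)

    def __str__(self) -> str:
        return serialize_gene_model_id(self)


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------


def _split_fields(s: str) -> list[tuple[str, int]]:
    """Split on periods, returning (token, start offset) pairs."""
    out = []
    pos = 0
    for tok in s.split("."):
        out.append((tok, pos))
        pos += len(tok) + 1
    return out


def parse_assembly_name(s: str, profile: str = "strict") -> AssemblyName:
    """Parse a dotted assembly name.

    The ``strict`` profile requires all 4 mandatory fields (species,
    individual, project group, version); ``compat`` tolerates an absent group
    and absent minor version, as in converted legacy names.
    """
    if profile not in ("strict", "compat"):
        raise ValueError(f"unknown profile {profile!r}")
    if not s:
        raise IdentifierError("empty identifier", code="EMPTY")
    if re.search(r"\s", s):
        raise IdentifierError(f"identifier {s!r} contains whitespace", code="WHITESPACE")
    fields_ = _split_fields(s)
    for tok, off in fields_:
        if tok == "":
            raise IdentifierError(f"empty field at offset {off} in {s!r}", code="EMPTY_FIELD", span=(off, off))
    tokens = [t for t, _ in fields_]
    try:
        tolid = ToLID.parse(tokens[0])
    except IdentifierError as e:
        raise IdentifierError(
            f"malformed ToLID prefix {tokens[0]!r} in {s!r} (characters 0-{len(tokens[0])})",
            code="TOLID",
            span=(0, len(tokens[0])),
        ) from e
    if len(tokens) < 3:
        raise IdentifierError(f"{s!r} has {len(tokens)} fields; at least ToLID.sample.version required", code="TOO_FEW_FIELDS")

    sample = _check_token(tokens[1], "sample name")
    idx = 2
    group: Optional[str] = None
    if VERSION_RE.fullmatch(tokens[idx]):
        if profile == "strict":
            raise IdentifierError(
                f"{s!r} lacks a sequencing-group field; strict names contain at least 4 fields "
                "(species, individual, project group, version)",
                code="MISSING_GROUP",
            )
    else:
        group = _check_token(tokens[idx], "sequencing group")
        idx += 1
        if idx >= len(tokens):
            raise IdentifierError(f"{s!r} has no version field", code="NO_VERSION")
    m = VERSION_RE.fullmatch(tokens[idx])
    if not m:
        raise IdentifierError(f"expected version field, got {tokens[idx]!r} in {s!r}", code="NO_VERSION")
    has_v = m.group(1) == "v"
    major = int(m.group(2))
    idx += 1
    minor: Optional[int] = None
    if idx < len(tokens) and MINOR_RE.fullmatch(tokens[idx]):
        minor = int(tokens[idx])
        idx += 1
    extras = tuple(_check_token(t, "extra field") for t in tokens[idx:])
    return AssemblyName(
        tolid=tolid,
        sample_name=sample,
        group=group,
        version_major=major,
        version_minor=minor,
        has_v_prefix=has_v,
        extras=extras,
    )


def serialize_assembly_name(a: AssemblyName, style: str = "canonical") -> str:
    """Serialize an assembly name.

    ``canonical`` emits every present field; ``compat`` omits the sequencing
    group (converted-legacy table style).
    """
    if style not in ("canonical", "compat"):
        raise ValueError(f"unknown style {style!r}")
    if style == "compat" and a.group is not None:
        a = replace(a, group=None)
    return ".".join(a.fields())


def parse_gene_model_id(s: str) -> GeneModelID:
    """Parse a gene-model or transcript identifier.

    Works from the right: optional transcript ordinal, entity token, region,
    annotation version, then the remaining prefix as a compat assembly name.
    A single empty slot between region and entity (the legacy-table "01.."
    dialect) is accepted and normalized to "no subgenome".
    """
    if not s:
        raise IdentifierError("empty identifier", code="EMPTY")
    if re.search(r"\s", s):
        raise IdentifierError(f"identifier {s!r} contains whitespace", code="WHITESPACE")
    tokens = s.split(".")
    transcript: Optional[int] = None
    ei = len(tokens) - 1
    if ei >= 1 and MINOR_RE.fullmatch(tokens[ei]) and ENTITY_RE.fullmatch(tokens[ei - 1]):
        transcript = int(tokens[ei])
        if transcript < 1:
            raise IdentifierError(f"transcript number must be >= 1 in {s!r}", code="TRANSCRIPT")
        ei -= 1
    m = ENTITY_RE.fullmatch(tokens[ei])
    if not m:
        em = re.fullmatch(r"([A-Za-z]*?)([A-Za-z])([0-9]+)", tokens[ei])
        if em:
            raise IdentifierError(
                f"unknown entity letter {em.group(2)!r} in {tokens[ei]!r}; allowed entity types: "
                f"{', '.join(ENTITY_TYPES)}",
                code="ENTITY",
            )
        raise IdentifierError(
            f"cannot read entity token {tokens[ei]!r} in {s!r}: expected optional prefix letter, "
            f"an entity type ({', '.join(ENTITY_TYPES)}) and a numeric entity number",
            code="ENTITY",
        )
    prefix, etype, digits = m.groups()
    ri = ei - 1
    if ri >= 0 and tokens[ri] == "":
        ri -= 1  # tolerated empty subgenome slot, normalized away
    if ri < 2:
        raise IdentifierError(f"{s!r} is too short to contain assembly, annotation and region fields", code="TOO_FEW_FIELDS")
    region = SeqRegion.parse(tokens[ri])
    ai = ri - 1
    if not MINOR_RE.fullmatch(tokens[ai]) or int(tokens[ai]) < 1:
        raise IdentifierError(f"expected a numeric annotation version before the region, got {tokens[ai]!r}", code="VERSION")
    annotation = AnnotationVersion(int(tokens[ai]))
    assembly = parse_assembly_name(".".join(tokens[:ai]), profile="compat")
    return GeneModelID(
        assembly=assembly,
        annotation=annotation,
        region=region,
        entity_type=etype,
        entity_number=int(digits),
        entity_prefix=prefix or None,
        entity_pad_width=len(digits),
        transcript_number=transcript,
    )


def serialize_gene_model_id(g: GeneModelID, dialect: str = "canonical") -> str:
    """Serialize a gene-model identifier.

    ``canonical`` never emits an empty dotted slot.  ``table3`` reproduces the
    legacy-table dialect that leaves an empty slot after the region when the
    region carries neither subgenome nor haplotype ("01..g000100"); it is
    accepted on parse but only emitted on request.
    """
    if dialect not in ("canonical", "table3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parts = list(g.assembly.fields())
    parts.append(str(g.annotation))
    parts.append(str(g.region))
    if dialect == "table3" and g.region.subgenome is None and g.region.haplotype is None:
        parts.append("")
    parts.append(g.entity_token())
    if g.transcript_number is not None:
        parts.append(str(g.transcript_number))
    return ".".join(parts)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    span: Optional[tuple[int, int]] = None


@dataclass
class ValidationReport:
    identifier: str
    issues: list[Issue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.issues

    @property
    def has_errors(self) -> bool:
        return any(i.severity == "error" for i in self.issues)

    def add(self, severity: str, code: str, message: str, span: Optional[tuple[int, int]] = None) -> None:
        self.issues.append(Issue(severity, code, message, span))


_NAME_CHARSET_RE = re.compile(r"[^A-Za-z0-9._-]")


def validate_name(
    s: str,
    profile: str = "insdc",
    stop_list: Iterable[str] = (),
    max_length: int = DEFAULT_MAX_LENGTH,
) -> ValidationReport:
    """Check an identifier against repository constraints; pure, never raises.

    All profiles check length, permitted characters, whitespace, empty fields
    and the taxonomy stop-list (repositories reject taxonomic names embedded
    in assembly/gene names — reported as a TAXON_TERM warning).  ``strict``
    and ``compat`` additionally require the string to parse as an assembly
    name or gene-model ID under the corresponding grammar profile; a missing
    sequencing group under ``strict`` is downgraded to a warning because
    widely used converted-legacy names omit it.
    """
    if profile not in ("insdc", "strict", "compat"):
        raise ValueError(f"unknown profile {profile!r}")
    rep = ValidationReport(identifier=s)
    if not s:
        rep.add("error", "EMPTY", "identifier is empty")
        return rep
    ws = re.search(r"\s", s)
    if ws:
        rep.add("error", "WHITESPACE", "identifier contains whitespace", span=(ws.start(), ws.end()))
    for m in _NAME_CHARSET_RE.finditer(s):
        if not m.group().isspace():
            rep.add("error", "CHARSET", f"character {m.group()!r} not in [A-Za-z0-9._-]", span=(m.start(), m.end()))
    if len(s) > max_length:
        rep.add("error", "TOO_LONG", f"length {len(s)} exceeds maximum {max_length}", span=(max_length, len(s)))
    stop = {w.lower() for w in stop_list}
    for tok, off in _split_fields(s):
        if tok == "":
            rep.add("error", "EMPTY_FIELD", f"empty field at offset {off}", span=(off, off))
        elif tok.lower() in stop:
            rep.add("warning", "TAXON_TERM", f"field {tok!r} matches a taxonomy stop-list term", span=(off, off + len(tok)))
    if profile in ("strict", "compat") and not rep.has_errors:
        try:
            parse_assembly_name(s, profile=profile)
        except IdentifierError as e_asm:
            if e_asm.code == "MISSING_GROUP":
                rep.add("warning", "MISSING_GROUP", str(e_asm), span=e_asm.span)
            else:
                try:
                    parse_gene_model_id(s)
                except IdentifierError:
                    rep.add("error", e_asm.code, str(e_asm), span=e_asm.span)
    return rep


def report_to_tsv(reports: Sequence[ValidationReport]) -> str:
    """One TSV row per issue: identifier, severity, code, message."""
    lines = ["identifier\tseverity\tcode\tmessage"]
    for rep in reports:
        if not rep.issues:
            lines.append(f"{rep.identifier}\tok\t\t")
        for issue in rep.issues:
            lines.append(f"{rep.identifier}\t{issue.severity}\t{issue.code}\t{issue.message}")
    return "\n".join(lines) + "\n"


def report_to_jsonl(reports: Sequence[ValidationReport]) -> str:
    out = []
    for rep in reports:
        out.append(
            json.dumps(
                {
                    "identifier": rep.identifier,
                    "valid": rep.valid,
                    "issues": [
                        {"severity": i.severity, "code": i.code, "message": i.message, "span": list(i.span) if i.span else None}
                        for i in rep.issues
                    ],
                },
                sort_keys=True,
            )
        )
    return "\n".join(out) + "\n"


def sanitize_token(token: str) -> str:
    """Replace characters forbidden inside a dotted field with '-'."""
    return re.sub(r"[^A-Za-z0-9_-]", "-", token)
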