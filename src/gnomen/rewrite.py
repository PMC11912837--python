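"""Batch-rename GFF3 annotation (and matching FASTA headers) to the new scheme.

Gene features receive serialized gene-model identifiers with entity numbers
assigned sequentially along each chromosome (default 10, 20, 30, ... —
leaving insertion room, with the attested six-digit zero padding), so that
adjacent numbers mean adjacent gene models.  Transcript children become
``<gene ID>.<ordinal>`` with ordinals assigned by start position; no legacy
canonical-transcript designation is assumed or preserved.  ``Parent``
attributes are updated consistently and the old ID can be kept as a Dbxref
cross-reference for provenance.

Rewriting is deliberately a line-level edit: only the ``ID``, ``Parent`` and
(optionally) ``Dbxref`` attribute values change; every other byte of the
input — column order, attribute order, spacing, comments, FASTA wrapping and
residues — passes through untouched.  Coordinates stay GFF3-native (1-based,
inclusive); no coordinate conversion ever happens here.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .identifiers import (
    AnnotationVersion,
    AssemblyName,
    GeneModelID,
    IdentifierError,
    SeqRegion,
    parse_gene_model_id,
    sanitize_token,
    serialize_gene_model_id,
)

__all__ = [
    "FeatureRecord",
    "NumberingPolicy",
    "RenameMap",
    "assign_numbers",
    "rewrite_gff3",
    "rewrite_fasta_headers",
    "generate_fixture",
    "rename_map_to_tsv",
    "seqid_to_region",
]

logger = logging.getLogger(__name__)

# feature types renamed as transcripts (children of genes)
TRANSCRIPT_TYPES = frozenset({"mRNA", "transcript"})


@dataclass
class FeatureRecord:
    """One parsed GFF3 feature line (coordinates 1-based inclusive)."""

    seqid: str
    feature_type: str
    start: int
    end: int
    strand: str
    id: Optional[str]
    parent_ids: tuple[str, ...]
    line_no: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise IdentifierError(f"feature at line {self.line_no}: start {self.start} > end {self.end}", code="GFF3")


@dataclass(frozen=True)
class NumberingPolicy:
    """How entity numbers are assigned along each sequence.

    Sequential mode numbers ``start, start+step, ...`` in positional order
    (seqid natural order, start ascending, end descending, then ID), restarting
    per seqid.  Random mode draws unique seeded numbers instead, for
    communities that prefer position-free identifiers.
    """

    start: int = 10
    step: int = 10
    width: int = 6
    mode: str = "sequential"  # "sequential" | "random"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IdentifierError("numbering start must be >= 0", code="POLICY")
        if self.step < 1:
            raise IdentifierError("numbering step must be >= 1", code="POLICY")
        if self.width < 1:
            raise IdentifierError("numbering width must be >= 1", code="POLICY")
        if self.mode not in ("sequential", "random"):
            raise IdentifierError(f"unknown numbering mode {self.mode!r}", code="POLICY")

    @property
    def capacity(self) -> int:
        """How many genes fit on one sequence under this policy."""
        return (10**self.width - self.start - 1) // self.step + 1


@dataclass
class RenameMap:
    """Ordered old->new identifier pairs with feature coordinates."""

    entries: list[dict] = field(default_factory=list)

    def add(self, old_id: str, new_id: str, feature_type: str, seqid: str, start: int, end: int) -> None:
        self.entries.append(
            {"old_id": old_id, "new_id": new_id, "feature_type": feature_type, "seqid": seqid, "start": start, "end": end}
        )

    def as_dict(self) -> dict[str, str]:
        return {e["old_id"]: e["new_id"] for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def rename_map_to_tsv(rmap: RenameMap) -> str:
    lines = ["old_id\tnew_id\tfeature_type\tseqid\tstart\tend"]
    for e in rmap.entries:
        lines.append(f"{e['old_id']}\t{e['new_id']}\t{e['feature_type']}\t{e['seqid']}\t{e['start']}\t{e['end']}")
    return "\n".join(lines) + "\n"


def _natural_key(s: str):
    return tuple((0, int(part)) if part.isdigit() else (1, part.lower()) for part in re.split(r"(\d+)", s) if part != "")


def _position_key(f: FeatureRecord):
    # start ascending, longer feature first on ties, ID as final tie-break
    return (_natural_key(f.seqid), f.start, -f.end, f.id or "")


def assign_numbers(features: Sequence[FeatureRecord], policy: NumberingPolicy = NumberingPolicy()) -> dict[str, int]:
    """Entity numbers for gene-level features, restarting per seqid.

    Sequential numbers increase monotonically with position within each
    seqid.  Raises when a seqid holds more genes than the policy's width
    allows, suggesting a larger width.
    """
    ordered = sorted(features, key=_position_key)
    per_seqid: dict[str, list[FeatureRecord]] = {}
    for f in ordered:
        per_seqid.setdefault(f.seqid, []).append(f)
    numbers: dict[str, int] = {}
    rng = random.Random(policy.seed) if policy.mode == "random" else None
    for seqid, feats in per_seqid.items():
        if len(feats) > policy.capacity:
            raise IdentifierError(
                f"{len(feats)} genes on {seqid} exceed the {policy.capacity} numbers available with "
                f"width={policy.width}, start={policy.start}, step={policy.step}; increase the width",
                code="NUMBER_OVERFLOW",
            )
        if rng is not None:
            drawn = rng.sample(range(policy.start, 10**policy.width), len(feats))
        else:
            drawn = [policy.start + i * policy.step for i in range(len(feats))]
        for f, n in zip(feats, drawn):
            numbers[f.id] = n
    return numbers


def seqid_to_region(seqid: str, pad_width: int = 2) -> SeqRegion:
    """Map a GFF3 seqid to a region: chromosome-like ids become padded digits,
    anything else is an unplaced scaffold with a sanitized token."""
    m = re.fullmatch(r"(?:[Cc]hr(?:omosome)?[_-]?)?0*(\d+)", seqid)
    if m and int(m.group(1)) > 0:
        number = int(m.group(1))
        return SeqRegion(kind="chromosome", number=number, pad_width=max(pad_width, len(str(number))))
    return SeqRegion(kind="scaffold", number=sanitize_token(seqid), pad_width=1)


# ---------------------------------------------------------------------------
# GFF3 attribute-column surgery
# ---------------------------------------------------------------------------


def _attr_value(col9: str, key: str) -> Optional[str]:
    for part in col9.rstrip(";").split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def _edit_attrs(col9: str, rename: Mapping[str, str], keep_old: bool, dbxref_prefix: str) -> str:
    """Rewrite ID/Parent values through ``rename``; optionally record the old
    ID under Dbxref.  Attribute order and unknown attributes are untouched."""
    trailing = col9.endswith(";")
    parts = col9.rstrip(";").split(";")
    old_id: Optional[str] = None
    renamed = False
    for i, part in enumerate(parts):
        if part.startswith("ID="):
            value = part[3:]
            if value in rename:
                old_id = value
                parts[i] = "ID=" + rename[value]
                renamed = True
        elif part.startswith("Parent="):
            values = part[7:].split(",")
            parts[i] = "Parent=" + ",".join(rename.get(v, v) for v in values)
    if keep_old and renamed and old_id is not None:
        xref = f"{dbxref_prefix}:{old_id}"
        for i, part in enumerate(parts):
            if part.startswith("Dbxref="):
                parts[i] = part + "," + xref
                break
        else:
            parts.append("Dbxref=" + xref)
    return ";".join(parts) + (";" if trailing else "")


def _as_lines(source: Union[str, Iterable[str]]) -> list[str]:
    if isinstance(source, str):
        return source.splitlines()
    return [line.rstrip("\n") for line in source]


def _scan_features(lines: Sequence[str]) -> list[tuple[int, list[str], FeatureRecord]]:
    """Parse feature lines; returns (line index, columns, record) triples."""
    out = []
    for idx, line in enumerate(lines):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise IdentifierError(f"line {idx + 1}: expected 9 tab-separated columns, found {len(cols)}", code="GFF3")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise IdentifierError(f"line {idx + 1}: non-numeric coordinates", code="GFF3") from None
        fid = _attr_value(cols[8], "ID")
        parent = _attr_value(cols[8], "Parent")
        rec = FeatureRecord(
            seqid=cols[0],
            feature_type=cols[2],
            start=start,
            end=end,
            strand=cols[6],
            id=fid,
            parent_ids=tuple(parent.split(",")) if parent else (),
            line_no=idx + 1,
        )
        out.append((idx, cols, rec))
    return out


def _is_new_scheme(identifier: Optional[str]) -> bool:
    if not identifier:
        return False
    try:
        parse_gene_model_id(identifier)
        return True
    except IdentifierError:
        return False


def rewrite_gff3(
    source: Union[str, Iterable[str]],
    assembly: AssemblyName,
    annotation: Union[AnnotationVersion, int],
    policy: NumberingPolicy = NumberingPolicy(),
    *,
    keep_old: bool = False,
    dbxref_prefix: str = "Legacy",
    detect_new: bool = False,
    dialect: str = "canonical",
    chromosome_pad_width: int = 2,
    type_entity_map: Optional[Mapping[str, str]] = None,
) -> tuple[str, RenameMap]:
    """Rename gene and transcript features of a GFF3 document.

    Gene-level features (type ``gene``, plus any types in ``type_entity_map``
    mapped to their entity letter) get serialized gene-model IDs; their
    transcript children get ``<gene>.<ordinal>``.  With ``detect_new``,
    features whose ID already parses as a new-scheme identifier are left
    alone, making the operation idempotent.  With ``keep_old``, each renamed
    feature keeps its original ID as ``Dbxref=<prefix>:<old>``.

    Returns the rewritten document and the ordered :class:`RenameMap`.
    Raises on duplicate IDs and on Parent references that resolve to no ID.
    """
    if isinstance(annotation, int):
        annotation = AnnotationVersion(annotation)
    lines = _as_lines(source)
    scanned = _scan_features(lines)

    seen_ids: set[str] = set()
    for _, _, rec in scanned:
        if rec.id is not None:
            if rec.id in seen_ids:
                raise IdentifierError(f"line {rec.line_no}: duplicate ID {rec.id!r}", code="DUPLICATE_ID")
            seen_ids.add(rec.id)
    for _, _, rec in scanned:
        for pid in rec.parent_ids:
            if pid not in seen_ids:
                raise IdentifierError(
                    f"line {rec.line_no}: Parent {pid!r} does not reference any ID in the file",
                    code="DANGLING_PARENT",
                )

    entity_of = {"gene": "g"}
    if type_entity_map:
        entity_of.update(type_entity_map)

    genes = [
        rec
        for _, _, rec in scanned
        if rec.feature_type in entity_of and rec.id is not None and not (detect_new and _is_new_scheme(rec.id))
    ]
    numbers = assign_numbers(genes, policy)

    # gene-model IDs carry the major assembly version only
    from dataclasses import replace

    gene_assembly = replace(assembly, version_minor=None, extras=())

    rename: dict[str, str] = {}
    gene_new: dict[str, GeneModelID] = {}
    for rec in genes:
        gm = GeneModelID(
            assembly=gene_assembly,
            annotation=annotation,
            region=seqid_to_region(rec.seqid, pad_width=chromosome_pad_width),
            entity_type=entity_of[rec.feature_type],
            entity_number=numbers[rec.id],
            entity_pad_width=policy.width,
        )
        gene_new[rec.id] = gm
        rename[rec.id] = serialize_gene_model_id(gm, dialect=dialect)

    # transcript ordinals: per gene, by start position (ties: end desc, ID)
    by_gene: dict[str, list[FeatureRecord]] = {}
    for _, _, rec in scanned:
        if rec.feature_type in TRANSCRIPT_TYPES and rec.id is not None:
            if detect_new and _is_new_scheme(rec.id):
                continue
            for pid in rec.parent_ids:
                if pid in rename:
                    by_gene.setdefault(pid, []).append(rec)
                    break
    for pid, feats in by_gene.items():
        feats.sort(key=lambda f: (f.start, -f.end, f.id or ""))
        for ordinal, f in enumerate(feats, start=1):
            rename[f.id] = f"{rename[pid]}.{ordinal}"

    rmap = RenameMap()
    for _, _, rec in scanned:
        if rec.id in rename:
            rmap.add(rec.id, rename[rec.id], rec.feature_type, rec.seqid, rec.start, rec.end)

    out_lines = list(lines)
    for idx, cols, rec in scanned:
        new_col9 = _edit_attrs(cols[8], rename, keep_old, dbxref_prefix)
        if new_col9 != cols[8]:
            out_lines[idx] = "\t".join(cols[:8] + [new_col9])
    return "\n".join(out_lines) + ("\n" if out_lines else ""), rmap


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def rewrite_fasta_headers(
    source: Union[str, Iterable[str]],
    mapping: Union[RenameMap, Mapping[str, str]],
) -> tuple[str, list[str]]:
    """Replace FASTA record IDs per the rename map.

    Sequence order, residues and line wrapping are unchanged; only the first
    whitespace-delimited token of mapped headers is replaced.  Unmapped
    headers pass through with a logged warning; duplicate input headers are
    an error.  Returns (output text, list of unmapped IDs).
    """
    table = mapping.as_dict() if isinstance(mapping, RenameMap) else dict(mapping)
    lines = _as_lines(source)
    seen: set[str] = set()
    unmapped: list[str] = []
    out = []
    for line in lines:
        if line.startswith(">"):
            header = line[1:]
            fid, _, rest = header.partition(" ")
            if fid in seen:
                raise IdentifierError(f"duplicate FASTA header {fid!r}", code="DUPLICATE_ID")
            seen.add(fid)
            if fid in table:
                line = ">" + table[fid] + (" " + rest if rest else "")
            else:
                unmapped.append(fid)
                logger.warning("FASTA header %r has no entry in the rename map; passed through", fid)
        out.append(line)
    return "\n".join(out) + ("\n" if out else ""), unmapped


# ---------------------------------------------------------------------------
# synthetic fixture generation
# ---------------------------------------------------------------------------


def generate_fixture(
    n_chrom: int,
    genes_per_chrom: int,
    transcripts_per_gene: int,
    seed: int,
) -> tuple[str, str]:
    """Deterministic synthetic GFF3 + FASTA for exercising the rewriter.

    Emulates a typical plant-style annotation: nested gene -> mRNA -> exon
    features laid out along each chromosome with random intergenic gaps, and
    chromosome sequences of random nucleotides.  Legacy-flavoured feature IDs
    (``G<chrom>_<n>``) stand in for community identifiers.  Identical seeds
    give identical bytes.
    """
    if min(n_chrom, genes_per_chrom, transcripts_per_gene) < 0:
        raise IdentifierError("fixture counts must be >= 0", code="FIXTURE")
    rng = random.Random(seed)
    gff = ["##gff-version 3"]
    fasta_parts: list[str] = []
    for c in range(1, n_chrom + 1):
        seqid = str(c)
        pos = 1
        features: list[str] = []
        for g in range(1, genes_per_chrom + 1):
            pos += rng.randint(200, 2000)  # intergenic gap
            glen = rng.randint(300, 3000)
            start, end = pos, pos + glen - 1
            strand = rng.choice("+-")
            gid = f"G{c}_{g:04d}"
            features.append(f"{seqid}\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid};Name={gid}")
            for t in range(1, transcripts_per_gene + 1):
                tid = f"{gid}.m{t}"
                features.append(f"{seqid}\ttest\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={tid};Parent={gid}")
                mid = start + glen // 2
                features.append(f"{seqid}\ttest\texon\t{start}\t{mid}\t.\t{strand}\t.\tParent={tid}")
                features.append(f"{seqid}\ttest\texon\t{min(mid + 1, end)}\t{end}\t.\t{strand}\t.\tParent={tid}")
            pos = end
        seqlen = pos + rng.randint(100, 500)
        gff.append(f"##sequence-region {seqid} 1 {seqlen}")
        gff.extend(features)
        seq = "".join(rng.choice("ACGT") for _ in range(seqlen))
        fasta_parts.append(">" + seqid)
        fasta_parts.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    gff_text = "\n".join(gff) + "\n"
    fasta_text = ("\n".join(fasta_parts) + "\n") if fasta_parts else ""
    return gff_text, fasta_text
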