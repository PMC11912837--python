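"""Construct Tree-of-Life species codes (ToLIDs) from taxonomy.

A ToLID compresses a binomial into a fixed-budget code: rank + clade prefix
letters (a single letter for vertebrates), ``1 upper + up to 2 lower`` for the
genus, ``1 upper + up to 3 lower`` for the species epithet (up to 2 for
vertebrates), and an optional sequential sample number starting at 1.
Epithets shorter than the budget are used whole ("max" -> "Max").

Prefixes come from a bundled offline clade table, user-extensible via TSV;
no network registry is consulted, so uniqueness against the official ToLID
registry is not guaranteed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

from .identifiers import IdentifierError, ToLID

__all__ = [
    "TaxonDescriptor",
    "CladePrefixTable",
    "abbreviate_genus",
    "abbreviate_species",
    "build_tolid",
]


@dataclass(frozen=True)
class TaxonDescriptor:
    """Taxonomic inputs for ToLID construction.

    Either the rank/clade letters are given directly, or a ``clade`` keyword
    is resolved through a :class:`CladePrefixTable`.
    """

    genus: str
    species_epithet: str
    vertebrate: bool = False
    rank_letter: Optional[str] = None
    clade_letter: Optional[str] = None
    clade: Optional[str] = None

    def __post_init__(self) -> None:
        for name, value in (("genus", self.genus), ("species epithet", self.species_epithet)):
            if not value or not value.isalpha():
                raise IdentifierError(f"{name} must be alphabetic and non-empty, got {value!r}", code="TAXON")


class CladePrefixTable:
    """Clade keyword -> (1-2 letter prefix, vertebrate flag) mapping.

    Vertebrate entries carry single-letter prefixes (VGP legacy).
    """

    def __init__(self, mapping: Mapping[str, tuple[str, bool]]):
        self._mapping: dict[str, tuple[str, bool]] = {}
        for keyword, (prefix, vertebrate) in mapping.items():
            if not (prefix.isascii() and prefix.islower() and prefix.isalpha() and 1 <= len(prefix) <= 2):
                raise IdentifierError(f"clade prefix must be 1-2 lowercase letters, got {prefix!r}", code="CLADE")
            if vertebrate and len(prefix) != 1:
                raise IdentifierError(f"vertebrate clade prefix must be a single letter, got {prefix!r}", code="CLADE")
            self._mapping[keyword.lower()] = (prefix, vertebrate)

    def __contains__(self, keyword: str) -> bool:
        return keyword.lower() in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def lookup(self, keyword: str) -> tuple[str, bool]:
        try:
            return self._mapping[keyword.lower()]
        except KeyError:
            known = ", ".join(sorted(self._mapping))
            raise IdentifierError(
                f"clade keyword {keyword!r} not in the offline prefix table (known: {known}); "
                "supply the prefix letters directly or merge a custom table",
                code="CLADE",
            ) from None

    def merged(self, other: "CladePrefixTable") -> "CladePrefixTable":
        """A new table where ``other`` overrides/extends this one."""
        merged = dict(self._mapping)
        merged.update(other._mapping)
        return CladePrefixTable(merged)

    @classmethod
    def from_tsv(cls, source: Union[str, Path]) -> "CladePrefixTable":
        """Load a table from TSV columns: clade_keyword, prefix, vertebrate_flag."""
        text = Path(source).read_text()
        return cls._from_text(text)

    @classmethod
    def _from_text(cls, text: str) -> "CladePrefixTable":
        mapping: dict[str, tuple[str, bool]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise IdentifierError(f"bad clade table line: {line!r}", code="CLADE")
            keyword, prefix = parts[0], parts[1]
            vertebrate = len(parts) > 2 and parts[2].strip() in ("1", "true", "True", "yes")
            mapping[keyword] = (prefix, vertebrate)
        return cls(mapping)

    @classmethod
    def bundled(cls) -> "CladePrefixTable":
        """The offline table shipped with the package."""
        text = importlib.resources.files("gnomen").joinpath("data/clade_prefixes.tsv").read_text()
        return cls._from_text(text)


def abbreviate_genus(genus: str) -> str:
    """First letter uppercased + up to 2 further lowercase letters ("Hordeum" -> "Hor")."""
    if not genus or not genus.isalpha():
        raise IdentifierError(f"genus must be alphabetic and non-empty, got {genus!r}", code="TAXON")
    g = genus.lower()
    return g[0].upper() + g[1:3]


def abbreviate_species(epithet: str, vertebrate: bool = False) -> str:
    """First letter uppercased + up to 3 (2 for vertebrates) lowercase letters."""
    if not epithet or not epithet.isalpha():
        raise IdentifierError(f"species epithet must be alphabetic and non-empty, got {epithet!r}", code="TAXON")
    budget = 2 if vertebrate else 3
    e = epithet.lower()
    return e[0].upper() + e[1 : 1 + budget]


def build_tolid(
    taxon: TaxonDescriptor,
    sample_number: Optional[int] = None,
    table: Optional[CladePrefixTable] = None,
) -> ToLID:
    """Build a ToLID from a taxon descriptor.

    Rank/clade letters are taken from the descriptor when supplied, otherwise
    resolved from its ``clade`` keyword via ``table`` (default: the bundled
    offline table).  Inputs are case-normalized before abbreviation.
    """
    vertebrate = taxon.vertebrate
    if taxon.rank_letter is not None:
        rank, clade_letter = taxon.rank_letter, taxon.clade_letter
    elif taxon.clade is not None:
        prefix, table_vert = (table or CladePrefixTable.bundled()).lookup(taxon.clade)
        vertebrate = vertebrate or table_vert
        rank = prefix[0]
        clade_letter = prefix[1] if len(prefix) == 2 else None
    else:
        raise IdentifierError(
            "cannot resolve the clade prefix: supply rank_letter (and clade_letter), or a clade "
            "keyword present in the offline table, or merge a custom table entry",
            code="CLADE",
        )
    species_code = abbreviate_species(taxon.species_epithet, vertebrate=vertebrate)
    return ToLID(
        rank_letter=rank,
        clade_letter=clade_letter,
        genus_code=abbreviate_genus(taxon.genus),
        species_code=species_code,
        sample_number=sample_number,
    )
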