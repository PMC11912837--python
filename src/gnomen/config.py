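"""Configuration loading for batch conversion and the CLI.

Species metadata lives in a flat key-value file — INI sections keyed by
legacy scheme name (stdlib ``configparser`` grammar) or the equivalent JSON
object — and is turned into per-scheme :class:`~gnomen.convert.ConversionConfig`
values.  Explicit CLI flags always override file values.

Recognised keys per section: ``tolid`` (ready-made code) or ``genus`` /
``species`` / ``clade_prefix`` (or ``clade`` keyword) / ``vertebrate``;
``sample_name``; ``group``; ``assembly_version``; ``assembly_version_minor``;
``annotation_version``; ``chromosome_pad_width``; ``entity_pad_width``;
``chromosome`` (supplemental, for schemes that never encoded one).
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path
from typing import Optional, Union

from .convert import ConversionConfig
from .identifiers import IdentifierError, ToLID
from .tolid import CladePrefixTable, TaxonDescriptor

__all__ = ["load_species_configs", "section_to_config"]

_TRUE = {"1", "true", "yes", "on"}


def _read_sections(path: Union[str, Path]) -> dict[str, dict[str, str]]:
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        data = json.loads(text)
        return {name: {k: str(v) for k, v in section.items()} for name, section in data.items()}
    parser = configparser.ConfigParser()
    parser.read_string(text)
    return {name: dict(parser[name]) for name in parser.sections()}


def section_to_config(section: dict[str, str], clade_table: Optional[CladePrefixTable] = None) -> ConversionConfig:
    known = {
        "tolid",
        "genus",
        "species",
        "clade_prefix",
        "clade",
        "vertebrate",
        "sample_name",
        "group",
        "assembly_version",
        "assembly_version_minor",
        "annotation_version",
        "chromosome_pad_width",
        "entity_pad_width",
        "chromosome",
    }
    unknown = set(section) - known
    if unknown:
        raise IdentifierError(f"unknown config keys: {', '.join(sorted(unknown))}", code="CONFIG")

    tolid = taxon = None
    if "tolid" in section:
        tolid = ToLID.parse(section["tolid"])
    elif "genus" in section and "species" in section:
        vertebrate = section.get("vertebrate", "").lower() in _TRUE
        prefix = section.get("clade_prefix")
        if prefix:
            taxon = TaxonDescriptor(
                genus=section["genus"],
                species_epithet=section["species"],
                vertebrate=vertebrate,
                rank_letter=prefix[0],
                clade_letter=prefix[1] if len(prefix) > 1 else None,
            )
        else:
            taxon = TaxonDescriptor(
                genus=section["genus"],
                species_epithet=section["species"],
                vertebrate=vertebrate,
                clade=section.get("clade"),
            )

    def _int(key: str) -> Optional[int]:
        return int(section[key]) if key in section else None

    kwargs = {}
    for key in ("assembly_version",):
        if _int(key) is not None:
            kwargs[key] = _int(key)
    for key, default in (
        ("assembly_version_minor", 0),
        ("annotation_version", 1),
        ("chromosome_pad_width", 2),
        ("entity_pad_width", 6),
    ):
        kwargs[key] = _int(key) if _int(key) is not None else default

    supplemental = {}
    if "chromosome" in section:
        supplemental["chromosome"] = section["chromosome"]

    return ConversionConfig(
        tolid=tolid,
        taxon=taxon,
        clade_table=clade_table,
        sample_name=section.get("sample_name"),
        group=section.get("group"),
        supplemental=supplemental,
        **kwargs,
    )


def load_species_configs(
    path: Union[str, Path], clade_table: Optional[CladePrefixTable] = None
) -> dict[str, ConversionConfig]:
    """Per-scheme conversion configs from an INI or JSON file."""
    return {name: section_to_config(sec, clade_table) for name, sec in _read_sections(path).items()}
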