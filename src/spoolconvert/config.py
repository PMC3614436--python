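"""XML configuration model: converter definitions and path-filter rules.

The daemon is driven by a single XML file with two sections: a list of
converter programs (what command to run, which input extension it consumes,
which extension and subdirectory its output gets, and which host it runs on)
and a list of pass rules (packet-filter style: files are blocked by default,
and a rule passes files whose path metadata matches every filter it states to
one converter).

Schema::

    <fccConfiguration>
      <converterList>
        <converter converterID="28" converterDir="mgf" converterCmd="..."
                   converterOptions="..." fromFileExt=".raw" toFileExt=".mgf"
                   hostname="srv-1"/>
      </converterList>
      <rulesList>
        <rule converterID="28" project="p1000" omics="Proteomics"
              instrument="VELOS_1" user="jdoe" beginDate="20110101"
              endDate="20111231" keyword=".*ETD.*"/>
      </rulesList>
    </fccConfiguration>

Every rule attribute except ``converterID`` is optional; an absent or empty
attribute is a wildcard.  Dates are calendar days serialized as ``YYYYMMDD``.
Unknown attributes are ignored with a warning so that configs written by
newer tools keep working.
"""
from __future__ import annotations

import hashlib
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path

log = logging.getLogger(__name__)

DATE_FORMAT = "%Y%m%d"


class ConfigError(ValueError):
    """Malformed or invalid configuration."""


@dataclass(frozen=True)
class ConverterSpec:
    """One converter program binding."""

    converter_id: str
    converter_cmd: str
    converter_dir: str = ""
    converter_options: str = ""
    from_file_ext: str = ""
    to_file_ext: str = ""
    hostname: str = ""


@dataclass(frozen=True)
class FilterRule:
    """One pass rule; ``None`` fields are wildcards, all present filters are ANDed."""

    converter_id: str
    project: str | None = None
    area: str | None = None
    instrument: str | None = None
    user: str | None = None
    date_begin: date | None = None
    date_end: date | None = None
    pattern: str | None = None


@dataclass(frozen=True)
class Config:
    """Parsed configuration: ordered converters and rules.

    ``source_fingerprint`` is the SHA-256 of the file bytes the config was
    parsed from (empty for configs built in memory); it is excluded from
    equality so a round-tripped config compares equal to its original.
    """

    converters: tuple[ConverterSpec, ...] = ()
    rules: tuple[FilterRule, ...] = ()
    source_fingerprint: str = field(default="", compare=False)


_CONVERTER_ATTRS = {
    "converterID": "converter_id", "converterDir": "converter_dir",
    "converterCmd": "converter_cmd", "converterOptions": "converter_options",
    "fromFileExt": "from_file_ext", "toFileExt": "to_file_ext", "hostname": "hostname",
}
_RULE_ATTRS = {
    "converterID": "converter_id", "project": "project", "omics": "area",
    "instrument": "instrument", "user": "user", "beginDate": "date_begin",
    "endDate": "date_end", "keyword": "pattern",
}


def _parse_date(text: str, context: str) -> date:
    try:
        return datetime.strptime(text, DATE_FORMAT).date()
    except ValueError:
        raise ConfigError(f"{context}: bad date {text!r}, expected YYYYMMDD") from None


def _take_attrs(element: ET.Element, known: dict[str, str], kind: str) -> dict[str, str]:
    for name in element.attrib.keys() - known.keys():
        log.warning("ignoring unknown %s attribute %r", kind, name)
    return {known[n]: v for n, v in element.attrib.items() if n in known}


def _parse_rule(element: ET.Element) -> FilterRule:
    # empty-string attributes are wildcards, same as absent ones
    raw = {k: v for k, v in _take_attrs(element, _RULE_ATTRS, "rule").items() if v != ""}
    cid = raw.pop("converter_id", "")
    for key in ("date_begin", "date_end"):
        if key in raw:
            raw[key] = _parse_date(raw[key], f"rule for converter {cid!r}")
    return FilterRule(converter_id=cid, **raw)


def parse_config(path: str | Path) -> Config:
    """Parse and validate an XML configuration file.

    Raises :class:`ConfigError` naming line and column on malformed XML, and
    with the joined diagnostics when any invariant is violated.
    """
    data = Path(path).read_bytes()
    try:
        root = ET.fromstring(data)
    except ET.ParseError as exc:
        line, column = exc.position
        raise ConfigError(f"{path}: malformed XML at line {line}, column {column}") from exc
    converters = tuple(ConverterSpec(**_take_attrs(el, _CONVERTER_ATTRS, "converter"))
                       for el in root.iter("converter"))
    rules = tuple(_parse_rule(el) for el in root.iter("rule"))
    config = Config(converters, rules, hashlib.sha256(data).hexdigest())
    if problems := validate_config(config):
        raise ConfigError(f"{path}: " + "; ".join(problems))
    return config


def validate_config(config: Config) -> list[str]:
    """Return a diagnostic message per violated invariant (empty list if valid)."""
    problems: list[str] = []
    seen: set[str] = set()
    for conv in config.converters:
        cid = conv.converter_id
        if not cid or cid in seen:
            problems.append(f"converterID {cid!r} is empty or a duplicate")
        seen.add(cid)
        problems += [
            f"converter {cid!r}: extension {ext!r} must start with '.'"
            for ext in (conv.from_file_ext, conv.to_file_ext) if not ext.startswith(".")
        ]
        if "/" in conv.converter_dir or "\\" in conv.converter_dir:
            problems.append(f"converter {cid!r}: converterDir must be a single path component")
        if not conv.converter_dir and conv.to_file_ext == conv.from_file_ext:
            problems.append(f"converter {cid!r}: output would overwrite input")
    for index, rule in enumerate(config.rules):
        where = f"rule {index} (converter {rule.converter_id!r})"
        if rule.converter_id not in seen:
            problems.append(f"{where}: unknown converterID")
        if rule.date_begin and rule.date_end and rule.date_begin > rule.date_end:
            problems.append(f"{where}: beginDate after endDate")
        if rule.pattern is not None:
            try:
                re.compile(rule.pattern)
            except re.error as exc:
                problems.append(f"{where}: bad keyword pattern: {exc}")
    return problems


def write_config(config: Config, path: str | Path) -> None:
    """Serialize a valid config; the emitted file re-parses to an equal config."""
    if problems := validate_config(config):
        raise ConfigError("refusing to write invalid config: " + "; ".join(problems))
    root = ET.Element("fccConfiguration")
    conv_list = ET.SubElement(root, "converterList")
    for conv in config.converters:
        ET.SubElement(conv_list, "converter",
                      {xml: getattr(conv, attr) for xml, attr in _CONVERTER_ATTRS.items()})
    rule_list = ET.SubElement(root, "rulesList")
    for rule in config.rules:
        values = ((xml, getattr(rule, attr)) for xml, attr in _RULE_ATTRS.items())
        ET.SubElement(rule_list, "rule", {
            xml: value.strftime(DATE_FORMAT) if isinstance(value, date) else value
            for xml, value in values if value is not None
        })
    ET.indent(root)
    payload = ET.tostring(root, encoding="utf-8", xml_declaration=True)
    Path(path).write_bytes(payload)


def add_rule(config: Config, rule: FilterRule) -> Config:
    """Return a new config with ``rule`` appended; the original is unchanged."""
    candidate = replace(config, rules=config.rules + (rule,))
    if problems := validate_config(candidate):
        raise ConfigError("; ".join(problems))
    return candidate
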