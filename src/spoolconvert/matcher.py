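"""Packet-filter-style rule matching and iteration planning.

Candidates are blocked by default; each rule passes the files it matches to
its converter.  Unlike a firewall, *all* matching rules fire — a facility
typically runs instrument-wide standard rules and project-specific custom
rules over the same files, and one raw file may legitimately feed several
converters.  Overlapping rules that name the same converter collapse to a
single job (the earliest rule wins the ordinal).

A matched pair becomes a job only if it survives three skip checks, applied
in a fixed precedence so the skip counters are well defined:

1. the error ledger (a previous failed attempt — never retried),
2. the output file already exists (the idempotency rule),
3. the converter is bound to a different host (multi-host partitioning).
"""
from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path

from .config import Config, ConverterSpec, FilterRule
from .crawler import CandidateFile
from .executor import ErrorLedger, command_tokens


@dataclass(frozen=True)
class Job:
    """One planned conversion: input, converter, derived output, command."""

    input_path: str
    converter: ConverterSpec
    output_path: str
    rule_index: int
    command_preview: tuple[str, ...]


@dataclass(frozen=True)
class IterationPlan:
    jobs: tuple[Job, ...] = ()
    skipped_existing: int = 0
    skipped_errored: int = 0
    skipped_foreign_host: int = 0


def derive_output_path(input_path: str | Path, converter: ConverterSpec) -> str:
    """``dirname(input)/converterDir/stem + toFileExt``; touches nothing on disk.

    The stem removes exactly the ``fromFileExt`` suffix, so multi-dot names
    like ``a.b.raw`` keep their inner dots.
    """
    path = Path(input_path)
    if not path.name.endswith(converter.from_file_ext):
        raise ValueError(f"{path.name!r} lacks input extension {converter.from_file_ext!r}")
    stem = path.name[: len(path.name) - len(converter.from_file_ext)]
    directory = path.parent / converter.converter_dir if converter.converter_dir else path.parent
    return str(directory / (stem + converter.to_file_ext))


def _host_matches(converter_host: str, local_hostname: str | None) -> bool:
    # unqualified, case-insensitive; an unset converter hostname runs anywhere
    if local_hostname is None or not converter_host:
        return True
    return converter_host.split(".")[0].lower() == local_hostname.split(".")[0].lower()


def candidate_matches_rule(
    candidate: CandidateFile, rule: FilterRule, converter: ConverterSpec
) -> bool:
    """True iff the candidate carries the converter's input extension and
    every filter the rule states holds (exact match on project/area/
    instrument/user, inclusive date window, unanchored regex search over the
    relative path)."""
    if not candidate.relative_path.rsplit("/", 1)[-1].endswith(converter.from_file_ext):
        return False
    meta = candidate.metadata
    for want, have in ((rule.project, meta.project), (rule.area, meta.area),
                       (rule.instrument, meta.instrument), (rule.user, meta.user)):
        if want is not None and have != want:
            return False
    if rule.date_begin is not None or rule.date_end is not None:
        day = meta.acquired_date
        if day is None:
            return False
        if rule.date_begin is not None and day < rule.date_begin:
            return False
        if rule.date_end is not None and day > rule.date_end:
            return False
    if rule.pattern is not None and not re.search(rule.pattern, candidate.relative_path):
        return False
    return True


def plan_iteration(candidates: list[CandidateFile], config: Config,
                   local_hostname: str | None, ledger: ErrorLedger) -> IterationPlan:
    """Match every candidate against every rule and emit this iteration's jobs.

    ``local_hostname=None`` disables the host check and yields the all-hosts
    plan.  Duplicate (input, converter) matches from overlapping rules
    collapse to one job keeping the lowest rule index.
    """
    converters = {c.converter_id: c for c in config.converters}
    matched: dict[tuple[str, str], tuple[int, ConverterSpec]] = {}
    for candidate in candidates:
        for index, rule in enumerate(config.rules):
            converter = converters[rule.converter_id]
            key = (candidate.absolute_path, converter.converter_id)
            if key not in matched and candidate_matches_rule(candidate, rule, converter):
                matched[key] = (index, converter)
    jobs: list[Job] = []
    errored = existing = foreign = 0
    for (input_path, converter_id), (index, converter) in matched.items():
        if (input_path, converter_id) in ledger:
            errored += 1
            continue
        output_path = derive_output_path(input_path, converter)
        if os.path.exists(output_path):
            existing += 1
            continue
        if not _host_matches(converter.hostname, local_hostname):
            foreign += 1
            continue
        jobs.append(Job(input_path, converter, output_path, index,
                        command_tokens(converter, input_path, output_path)))
    return IterationPlan(tuple(jobs), existing, errored, foreign)
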