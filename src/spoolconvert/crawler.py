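"""Spool-directory crawler and path-metadata extraction.

Instruments push their raw output into a shared spool tree organized by the
facility naming convention ``project/area/instrument/user_date/filename``:
a unique project identifier, the -omics scientific area, the instrument
name, the operator and acquisition date joined as ``<user>_<YYYYMMDD>``,
and a filename whose underscore-separated tokens serve as descriptive
keywords (e.g. the fragmentation method, ``ETD`` or ``CID``).  The crawler
enumerates every entry whose *name* carries a configured input extension —
including directories, because some vendors (Waters) write a ``.raw``
*folder* — and parses this convention into metadata for rule matching.

Only entries older than ``min_age_seconds`` are reported, so files still
being copied from an instrument PC are never picked up half-written.
"""
from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Callable

from .config import DATE_FORMAT, Config

log = logging.getLogger(__name__)

DEFAULT_MIN_AGE_SECONDS = 300.0


@dataclass(frozen=True)
class PathMetadata:
    """Fields parsed from a spool-relative path; missing pieces are ``None``."""

    project: str | None = None
    area: str | None = None
    instrument: str | None = None
    user: str | None = None
    acquired_date: date | None = None
    keywords: tuple[str, ...] = ()

    @property
    def conforming(self) -> bool:
        """True iff the path carried every component of the naming convention."""
        return None not in (self.project, self.area, self.instrument, self.user, self.acquired_date)


@dataclass(frozen=True)
class CandidateFile:
    """A crawled entry (file or vendor bundle directory) plus its metadata."""

    absolute_path: str
    relative_path: str
    metadata: PathMetadata
    modified_age_seconds: float


def extract_path_metadata(relative_path: str) -> PathMetadata:
    """Parse the facility naming convention out of a ``/``-separated path.

    Components map positionally to project, area and instrument; the fourth
    is split on its *last* underscore into user and acquisition date (so
    instrument names like ``VELOS_1`` survive intact in their own component).
    Filename keywords are the underscore tokens of the basename with its
    final extension stripped.  Degenerate input never raises: whatever
    parsed is returned, and ``conforming`` is simply false.
    """
    parts = [p for p in relative_path.split("/") if p]
    name = parts[-1] if parts else ""
    stem = name.rsplit(".", 1)[0]
    fields: dict[str, object] = {}
    for label, value in zip(("project", "area", "instrument"), parts[:-1]):
        fields[label] = value
    if len(parts) >= 5:
        user, sep, day = parts[3].rpartition("_")
        fields["user"] = user if sep else parts[3]
        try:
            fields["acquired_date"] = datetime.strptime(day, DATE_FORMAT).date()
        except ValueError:
            pass
    return PathMetadata(keywords=tuple(t for t in stem.split("_") if t), **fields)


def crawl(
    root: str | Path,
    config: Config,
    min_age_seconds: float = DEFAULT_MIN_AGE_SECONDS,
    metadata_parser: Callable[[str], PathMetadata] = extract_path_metadata,
) -> list[CandidateFile]:
    """List every candidate under ``root``, sorted by relative path.

    A candidate is any file or directory whose name ends with one of the
    configured input extensions and whose modification age is at least
    ``min_age_seconds``.  Converter output directories are crawled like any
    other folder, so a converter's products can feed a later rule (multi-
    level workflows).  Directory candidates are treated as opaque vendor
    bundles and not descended into.  Unreadable subdirectories are skipped
    with a warning; an unreadable root raises.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"spool root {root} is not a directory")
    extensions = tuple({c.from_file_ext for c in config.converters if c.from_file_ext})
    now = time.time()
    candidates: list[CandidateFile] = []

    def report(error: OSError) -> None:  # noqa: E704 - one-line warning hook
        log.warning("skipping unreadable entry: %s", error)

    for dirpath, dirnames, filenames in os.walk(root, onerror=report):
        bundles = [d for d in dirnames if d.endswith(extensions)] if extensions else []
        for bundle in bundles:
            dirnames.remove(bundle)
        for name in filenames + bundles:
            if not extensions or not name.endswith(extensions):
                continue
            path = Path(dirpath, name)
            try:
                age = max(0.0, now - path.stat().st_mtime)
            except OSError as exc:
                report(exc)
                continue
            if age < min_age_seconds:
                continue
            relative = path.relative_to(root).as_posix()
            candidates.append(CandidateFile(str(path), relative, metadata_parser(relative), age))
    candidates.sort(key=lambda c: c.relative_path)
    return candidates
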