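from __future__ import annotations

from pathlib import Path

import pytest

from spoolconvert import (
    CandidateFile,
    Config,
    ConverterSpec,
    FilterRule,
    extract_path_metadata,
    write_config,
)


def converter(
    cid: str = "28",
    *,
    cmd: str = "/bin/true",
    cdir: str = "mgf",
    opts: str = "",
    from_ext: str = ".raw",
    to_ext: str = ".mgf",
    host: str = "",
) -> ConverterSpec:
    return ConverterSpec(cid, cmd, cdir, opts, from_ext, to_ext, host)


def wildcard_rule(cid: str = "28", **fields) -> FilterRule:
    return FilterRule(converter_id=cid, **fields)


def candidate(rel: str, base: str = "/spool") -> CandidateFile:
    """In-memory candidate for pure matcher tests (no filesystem)."""
    return CandidateFile(f"{base}/{rel}", rel, extract_path_metadata(rel), 1000.0)


@pytest.fixture
def config_file(tmp_path):
    """Write a Config to disk and return the path."""

    def _write(config: Config, name: str = "fcc.xml") -> Path:
        path = tmp_path / name
        write_config(config, path)
        return path

    return _write
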