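"""Bounded-pool job execution, the central log, and the error ledger.

Each job runs one external converter process.  The command is the converter
executable, its verbatim option string tokenized shell-style (double-quoted
groups stay one token), then the input and output paths; no shell ever
interprets it.  The converter writes to a temporary name and the executor
renames to the final output path only on success, so the planner's
"output already exists" idempotency check can never observe a partial file.

Every job appends exactly one tab-separated record to the central log, the
system's single piece of persistent state.  The error ledger — the set of
(input, converter) pairs whose most recent attempt failed — is rebuilt from
that log each iteration and keeps corrupt inputs from being retried forever.
"""
from __future__ import annotations

import logging
import os
import shlex
import shutil
import socket
import subprocess
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import astuple, dataclass
from datetime import datetime
from pathlib import Path
from typing import TYPE_CHECKING

from .config import ConfigError, ConverterSpec

if TYPE_CHECKING:  # pragma: no cover
    from .matcher import IterationPlan, Job

log = logging.getLogger(__name__)

TEMP_SUFFIX = ".part"
_STATUSES = ("success", "failure")


@dataclass(frozen=True)
class JobResult:
    job: "Job"
    status: str
    return_code: int
    started_at: float
    finished_at: float
    host: str


@dataclass(frozen=True)
class LogRecord:
    """One line of the central log (tab-separated, in field order)."""

    timestamp: str
    host: str
    converter_id: str
    input_path: str
    output_path: str
    status: str
    return_code: int
    duration_seconds: float


@dataclass(frozen=True)
class ErrorLedger:
    """(input_path, converter_id) pairs whose latest attempt failed."""

    entries: frozenset[tuple[str, str]] = frozenset()

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries


def command_tokens(converter: ConverterSpec, input_path: str, output_path: str) -> tuple[str, ...]:
    """Assemble the argv for one conversion; raises on unbalanced quotes."""
    try:
        options = shlex.split(converter.converter_options)
    except ValueError as exc:
        raise ConfigError(
            f"converter {converter.converter_id!r}: bad converterOptions: {exc}"
        ) from exc
    return (converter.converter_cmd, *options, str(input_path), str(output_path))


def build_command(job: "Job") -> tuple[str, ...]:
    return command_tokens(job.converter, job.input_path, job.output_path)


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    return text.replace("\\n", "\n").replace("\\t", "\t").replace("\\\\", "\\")


def format_record(record: LogRecord) -> str:
    return "\t".join(_escape(str(field)) for field in astuple(record)) + "\n"


def parse_record(line: str) -> LogRecord | None:
    """Parse one log line; malformed input yields ``None``, never an exception."""
    parts = [_unescape(p) for p in line.rstrip("\n").split("\t")]
    if len(parts) != 8 or parts[5] not in _STATUSES:
        return None
    try:
        return LogRecord(*parts[:6], int(parts[6]), float(parts[7]))
    except ValueError:
        return None


def _run_job(job: "Job", host: str) -> JobResult:
    output = Path(job.output_path)
    temp = output.with_name(output.name + TEMP_SUFFIX)
    started = time.time()
    output.parent.mkdir(parents=True, exist_ok=True)
    try:
        argv = command_tokens(job.converter, job.input_path, str(temp))
        code = subprocess.run(argv, stdout=subprocess.DEVNULL, stderr=subprocess.DEVNULL).returncode
    except (OSError, ConfigError) as exc:
        log.warning("job %s failed to launch: %s", job.input_path, exc)
        code = 127
    if code == 0 and temp.exists():
        os.replace(temp, output)
        status = "success"
    else:
        shutil.rmtree(temp) if temp.is_dir() else temp.unlink(missing_ok=True)
        status = "failure"
    return JobResult(job, status, code, started, time.time(), host)


def execute_plan(plan: "IterationPlan", pool_size: int | None = None,
                 log_path: str | Path = "conversion.log",
                 host: str | None = None) -> list[JobResult]:
    """Run every planned job on at most ``pool_size`` concurrent workers.

    Returns after all jobs finish (the iteration barrier).  Each result is
    appended to the central log under a lock as soon as its job ends; an
    unwritable log aborts the iteration before anything runs.  The final
    filesystem state is independent of ``pool_size``.
    """
    if not plan.jobs:
        return []
    pool_size = pool_size or os.cpu_count() or 1
    host = host or socket.gethostname()
    log_file = open(log_path, "a", encoding="utf-8")  # noqa: SIM115 - held across workers
    lock = threading.Lock()
    results: list[JobResult | None] = [None] * len(plan.jobs)

    def worker(index: int, job: "Job") -> None:
        result = _run_job(job, host)
        record = LogRecord(
            datetime.fromtimestamp(result.finished_at).isoformat(timespec="seconds"),
            host, job.converter.converter_id, job.input_path, job.output_path,
            result.status, result.return_code,
            round(result.finished_at - result.started_at, 3))
        with lock:
            log_file.write(format_record(record))
            log_file.flush()
        results[index] = result

    try:
        with ThreadPoolExecutor(max_workers=pool_size) as pool:
            futures = [pool.submit(worker, i, job) for i, job in enumerate(plan.jobs)]
            for future in futures:
                future.result()
    finally:
        log_file.close()
    return [r for r in results if r is not None]


def load_ledger(log_path: str | Path) -> ErrorLedger:
    """Rebuild the error ledger from the central log (absent log: empty ledger).

    A single pass replays the records in order: a failure adds its
    (input, converter) pair, a later success for the same pair clears it.
    Malformed lines are skipped with a warning, never fatally.
    """
    path = Path(log_path)
    if not path.exists():
        return ErrorLedger()
    failed: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as handle:
        for number, line in enumerate(handle, start=1):
            record = parse_record(line) if line.strip() else None
            if record is None:
                if line.strip():
                    log.warning("skipping malformed log line %d", number)
                continue
            pair = (record.input_path, record.converter_id)
            failed.add(pair) if record.status == "failure" else failed.discard(pair)
    return ErrorLedger(frozenset(failed))
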