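"""The daemon loop: parse → crawl → match → execute, repeated forever.

Each iteration re-parses the configuration file, so edits (new rules, new
converters, new hosts) take effect in the next iteration without a restart.
The system is crash-only: all persistent state is the spool tree plus the
central log, so killing the daemon between iterations loses nothing.  On a
fully processed static tree every iteration plans zero jobs — the loop is a
fixed point, and an L-stage workflow chain converges in L iterations.
"""
from __future__ import annotations

import logging
import os
import socket
import time
from dataclasses import dataclass, field
from pathlib import Path

from .config import Config, ConfigError, parse_config
from .crawler import DEFAULT_MIN_AGE_SECONDS, crawl
from .executor import ErrorLedger, JobResult, execute_plan, load_ledger, parse_record
from .matcher import IterationPlan, plan_iteration

log = logging.getLogger(__name__)

DEFAULT_LOG_NAME = "conversion.log"


@dataclass
class RunSettings:
    config_path: str
    spool_root: str
    local_hostname: str = field(default_factory=socket.gethostname)
    pool_size: int = field(default_factory=lambda: os.cpu_count() or 1)
    min_age_seconds: float = DEFAULT_MIN_AGE_SECONDS
    loop_interval_seconds: float = 30.0
    mode: str = "once"  # once | loop | dry-run
    log_path: str | None = None
    retry_errors: bool = False

    def resolved_log_path(self) -> Path:
        return Path(self.log_path) if self.log_path else Path(self.spool_root) / DEFAULT_LOG_NAME


@dataclass(frozen=True)
class IterationReport:
    plan: IterationPlan
    results: tuple[JobResult, ...] = ()


def run_once(settings: RunSettings, config: Config | None = None) -> IterationReport:
    """Run one full iteration; in dry-run mode plan only, executing nothing."""
    config = config if config is not None else parse_config(settings.config_path)
    candidates = crawl(settings.spool_root, config, settings.min_age_seconds)
    log_path = settings.resolved_log_path()
    ledger = ErrorLedger() if settings.retry_errors else load_ledger(log_path)
    plan = plan_iteration(candidates, config, settings.local_hostname, ledger)
    if settings.mode == "dry-run":
        return IterationReport(plan)
    results = execute_plan(plan, settings.pool_size, log_path, settings.local_hostname)
    return IterationReport(plan, tuple(results))


def run_loop(settings: RunSettings, max_iterations: int | None = None) -> int:
    """Repeat :func:`run_once` until interrupted (or ``max_iterations`` done).

    The config is re-parsed every iteration; if an edit left it transiently
    unparseable, the previous good config is kept and the loop continues.
    An interrupt finishes the current iteration's jobs, then returns the
    number of completed iterations.
    """
    config: Config | None = None
    completed = 0
    while max_iterations is None or completed < max_iterations:
        try:
            config = parse_config(settings.config_path)
        except ConfigError as exc:
            if config is None:
                raise
            log.warning("config re-parse failed, keeping previous: %s", exc)
        try:
            report = run_once(settings, config)
            log.info("iteration %d: %d jobs", completed + 1, len(report.plan.jobs))
        except KeyboardInterrupt:
            break
        completed += 1
        if completed != max_iterations:
            try:
                time.sleep(settings.loop_interval_seconds)
            except KeyboardInterrupt:
                break
    return completed


def status(log_path: str | Path, recent: int = 10) -> dict:
    """Summarize the central log: per-converter success/failure counts,
    the most recent failures, and the number of unparsable lines."""
    converters: dict[str, dict[str, int]] = {}
    failures, unparsable = [], 0
    path = Path(log_path)
    if path.exists():
        with path.open(encoding="utf-8") as handle:
            for line in handle:
                if not line.strip():
                    continue
                record = parse_record(line)
                if record is None:
                    unparsable += 1
                    continue
                bucket = converters.setdefault(record.converter_id, {"success": 0, "failure": 0})
                bucket[record.status] += 1
                if record.status == "failure":
                    failures.append((record.timestamp, record.converter_id, record.input_path))
    return {"converters": converters, "recent_failures": failures[-recent:],
            "unparsable_lines": unparsable}
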