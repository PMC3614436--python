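"""Executor: command assembly, pooled execution, log and ledger."""
from __future__ import annotations

import shlex
from pathlib import Path

import pytest

from spoolconvert import (
    Config,
    ConfigError,
    ErrorLedger,
    build_command,
    crawl,
    execute_plan,
    load_ledger,
    plan_iteration,
)
from spoolconvert.executor import TEMP_SUFFIX, LogRecord, format_record, parse_record
from spoolconvert.fixtures import call_count, make_mock_converter
from conftest import converter, wildcard_rule


def build_spool(tmp_path, rels=("p1/Proteomics/V_1/u_20110101/sample1.raw",)):
    root = tmp_path / "spool"
    for rel in rels:
        path = root / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(rel.encode())
    return root


def make_plan(root, config, ledger=ErrorLedger()):
    return plan_iteration(crawl(root, config, 0), config, None, ledger)


def mock_config(tmp_path, kind, opts=""):
    script = make_mock_converter(kind, tmp_path)
    return script, Config((converter(cmd=str(script), opts=opts),), (wildcard_rule(),))


class TestBuildCommand:
    def job(self, tmp_path, opts):
        root = build_spool(tmp_path)
        config = Config((converter(opts=opts),), (wildcard_rule(),))
        (job,) = make_plan(root, config).jobs
        return job

    def test_empty_options(self, tmp_path):
        job = self.job(tmp_path, "")
        assert build_command(job) == ("/bin/true", job.input_path, job.output_path)

    def test_quoted_group_stays_one_token(self, tmp_path):
        job = self.job(tmp_path, '--filter "peakPicking true 2-"')
        tokens = build_command(job)
        assert tokens[1:3] == ("--filter", "peakPicking true 2-")
        # round-trip through an independent shell-style tokenizer
        assert list(tokens[1:3]) == shlex.split('--filter "peakPicking true 2-"')

    def test_plain_flags_split_on_whitespace(self, tmp_path):
        job = self.job(tmp_path, "-a -b -c")
        assert build_command(job)[1:4] == ("-a", "-b", "-c") == tuple("-a -b -c".split())

    def test_unbalanced_quotes_is_configuration_error(self, tmp_path):
        root = build_spool(tmp_path)
        config = Config((converter(opts='--filter "oops'),), (wildcard_rule(),))
        with pytest.raises(ConfigError, match="converterOptions"):
            make_plan(root, config)


class TestExecutePlan:
    def test_copy_converter_produces_all_outputs(self, tmp_path):
        rels = [f"p1/Proteomics/V_1/u_20110101/s{n}.raw" for n in range(6)]
        root = build_spool(tmp_path, rels)
        _script, config = mock_config(tmp_path, "copy")
        results = execute_plan(make_plan(root, config), 4, tmp_path / "log")
        assert [r.status for r in results] == ["success"] * 6
        for result in results:
            job = result.job
            assert Path(job.output_path).read_bytes() == Path(job.input_path).read_bytes()
            assert result.return_code == 0 and result.finished_at >= result.started_at

    def test_directory_bundle_input_is_copied(self, tmp_path):
        root = tmp_path / "spool"
        bundle = root / "p1/Proteomics/V_1/u_20110101/waters.raw"
        bundle.mkdir(parents=True)
        (bundle / "_FUNC001.DAT").write_bytes(b"dat")
        _script, config = mock_config(tmp_path, "copy")
        (result,) = execute_plan(make_plan(root, config), 1, tmp_path / "log")
        assert result.status == "success"
        assert (Path(result.job.output_path) / "_FUNC001.DAT").read_bytes() == b"dat"

    def test_failure_leaves_no_output_and_enters_ledger(self, tmp_path):
        root = build_spool(tmp_path)
        _script, config = mock_config(tmp_path, "fail")
        log = tmp_path / "log"
        (result,) = execute_plan(make_plan(root, config), 2, log)
        assert result.status == "failure" and result.return_code == 1
        assert not Path(result.job.output_path).exists()
        assert (result.job.input_path, "28") in load_ledger(log)

    def test_partial_writer_is_cleaned_up(self, tmp_path):
        root = build_spool(tmp_path)
        _script, config = mock_config(tmp_path, "partial")
        (result,) = execute_plan(make_plan(root, config), 1, tmp_path / "log")
        assert result.status == "failure"
        assert not Path(result.job.output_path).exists()
        assert list(root.rglob(f"*{TEMP_SUFFIX}")) == []

    def test_missing_executable_fails_job_not_iteration(self, tmp_path):
        root = build_spool(
            tmp_path, ["p1/Proteomics/V_1/u_20110101/a.raw", "p1/Proteomics/V_1/u_20110101/b.raw"]
        )
        good = make_mock_converter("copy", tmp_path)
        config = Config(
            (converter("ok", cmd=str(good)), converter("gone", cmd="/no/such/bin", cdir="x")),
            (wildcard_rule("ok"), wildcard_rule("gone")),
        )
        results = execute_plan(make_plan(root, config), 2, tmp_path / "log")
        by_id = {r.job.converter.converter_id: r.status for r in results}
        assert by_id == {"ok": "success", "gone": "failure"}

    def test_empty_plan_touches_nothing(self, tmp_path):
        root = build_spool(tmp_path)
        config = Config((converter(),))  # no rules: default block
        log = tmp_path / "log"
        assert execute_plan(make_plan(root, config), 4, log) == []
        assert not log.exists()

    def test_unwritable_log_aborts_before_running(self, tmp_path):
        root = build_spool(tmp_path)
        script, config = mock_config(tmp_path, "copy")
        blocker = tmp_path / "file"
        blocker.write_text("")
        with pytest.raises(OSError):
            execute_plan(make_plan(root, config), 1, blocker / "log")
        assert call_count(script) == 0

    def test_final_state_independent_of_pool_size(self, tmp_path):
        rels = [f"p1/Proteomics/V_1/u_20110101/s{n}.raw" for n in range(5)]
        states = []
        for pool_size in (1, 2, 8):
            base = tmp_path / f"pool{pool_size}"
            base.mkdir()
            root = build_spool(base, rels)
            script = make_mock_converter("copy", base)
            fail = make_mock_converter("fail", base)
            config = Config(
                (converter(cmd=str(script)),
                 converter("9", cmd=str(fail), cdir="broken", to_ext=".txt")),
                (wildcard_rule(), wildcard_rule("9")),
            )
            log = base / "log"
            execute_plan(make_plan(root, config), pool_size, log)
            tree = sorted(p.relative_to(root).as_posix() for p in root.rglob("*"))
            ledger = {(Path(i).relative_to(root).as_posix(), c) for i, c in load_ledger(log).entries}
            states.append((tree, ledger))
        assert states[0] == states[1] == states[2]


class TestLogAndLedger:
    def record(self, input_path="/s/f.raw", cid="28", status="failure"):
        return LogRecord("2011-05-03T10:00:00", "srv", cid, input_path, "/s/m/f.mgf",
                         status, 0 if status == "success" else 1, 1.5)

    def test_record_roundtrip_with_separator_escaping(self):
        record = self.record(input_path="/s/odd\tname\n.raw")
        line = format_record(record)
        assert line.endswith("\n") and "\t".join(line.split("\t")).count("\n") == 1
        assert parse_record(line) == record

    def test_single_failure_enters_ledger(self, tmp_path):
        log = tmp_path / "log"
        log.write_text(format_record(self.record()))
        assert ("/s/f.raw", "28") in load_ledger(log)

    def test_later_success_clears_failure(self, tmp_path):
        log = tmp_path / "log"
        log.write_text(format_record(self.record()) + format_record(self.record(status="success")))
        assert load_ledger(log).entries == frozenset()

    def test_replay_semantics_match_sequence_oracle(self, tmp_path):
        sequence = [("a", "fail"), ("b", "fail"), ("a", "ok"), ("b", "fail"), ("c", "ok")]
        log = tmp_path / "log"
        log.write_text(
            "".join(
                format_record(self.record(input_path=f, status="failure" if s == "fail" else "success"))
                for f, s in sequence
            )
        )
        expected = set()
        for name, state in sequence:  # independent replay
            expected.add((name, "28")) if state == "fail" else expected.discard((name, "28"))
        assert load_ledger(log).entries == frozenset(expected)

    def test_absent_log_is_empty_ledger(self, tmp_path):
        assert load_ledger(tmp_path / "missing").entries == frozenset()

    def test_malformed_lines_are_skipped_with_warning(self, tmp_path, caplog):
        log = tmp_path / "log"
        log.write_text("not a record\n" + format_record(self.record()) + "also\tbad\n")
        with caplog.at_level("WARNING"):
            ledger = load_ledger(log)
        assert ledger.entries == frozenset({("/s/f.raw", "28")})
        assert sum("malformed" in m for m in caplog.messages) == 2

    def test_concurrent_jobs_never_interleave_within_a_record(self, tmp_path):
        rels = [f"p1/Proteomics/V_1/u_20110101/s{n}.raw" for n in range(8)]
        root = build_spool(tmp_path, rels)
        _script, config = mock_config(tmp_path, "copy")
        log = tmp_path / "log"
        execute_plan(make_plan(root, config), 8, log)
        lines = log.read_text().splitlines()
        assert len(lines) == 8
        assert all(parse_record(line + "\n") is not None for line in lines)
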