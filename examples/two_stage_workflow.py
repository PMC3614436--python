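"""Multi-level workflow: one converter's output feeds the next rule.

Stage A converts .raw files into .mgf peak lists; stage B post-processes
each .mgf into a .txt report.  Nothing special wires the stages together —
stage A's output directory is simply crawled like everything else, so its
products match stage B's rule on the following iteration.

Run with:  python examples/two_stage_workflow.py
"""
import tempfile
from pathlib import Path

from spoolconvert import (
    Config, ConverterSpec, FilterRule, RunSettings, SpoolSpec,
    generate_spool_tree, make_mock_converter, run_once, write_config,
)

with tempfile.TemporaryDirectory() as workdir:
    base = Path(workdir)
    root = base / "spool"
    generate_spool_tree(
        SpoolSpec(n_projects=1, instruments_per_area=1, files_per_leaf=2,
                  extensions=((".raw", 1.0),), noise_fraction=0.0, dir_fraction=0.0, seed=1),
        root,
    )
    cmd = str(make_mock_converter("copy", base))
    config = Config(
        converters=(
            ConverterSpec("A", cmd, "mgf", "", ".raw", ".mgf", ""),
            ConverterSpec("B", cmd, "report", "", ".mgf", ".txt", ""),
        ),
        rules=(FilterRule("A"), FilterRule("B", pattern="ETD")),
    )
    write_config(config, base / "fcc.xml")
    settings = RunSettings(config_path=str(base / "fcc.xml"), spool_root=str(root),
                           min_age_seconds=0, pool_size=2)

    for iteration in (1, 2, 3):
        report = run_once(settings)
        by_stage = {}
        for job in report.plan.jobs:
            by_stage[job.converter.converter_id] = by_stage.get(job.converter.converter_id, 0) + 1
        print(f"iteration {iteration}: jobs per stage {by_stage or '{}'}")

# Iteration 1 runs only stage A (no .mgf exists yet); iteration 2 runs stage
# B on the ETD-keyword subset of A's outputs; iteration 3 plans zero jobs —
# the chain has converged and the daemon idles until new raw files arrive.
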