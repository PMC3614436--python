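"""End-to-end tour: generate a spool tree, configure a converter, run twice.

Builds a synthetic spool directory in a temporary location, wires a mock
"converter" (a script that copies its input) to a wildcard rule, runs one
daemon iteration, and then runs a second one to show the idempotent fixed
point: work that is already done is never redone.

Run with:  python examples/quickstart.py
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
    manifest = generate_spool_tree(SpoolSpec(seed=1), root)
    print(f"spool tree: {len(manifest)} entries, e.g. {manifest[0]}")

    converter_cmd = make_mock_converter("copy", base)
    config = Config(
        converters=(ConverterSpec("28", str(converter_cmd), "mgf", "", ".raw", ".mgf", ""),),
        rules=(FilterRule(converter_id="28"),),  # wildcard: pass every .raw
    )
    write_config(config, base / "fcc.xml")

    settings = RunSettings(config_path=str(base / "fcc.xml"), spool_root=str(root),
                           min_age_seconds=0, pool_size=4)
    first = run_once(settings)
    done = sum(r.status == "success" for r in first.results)
    print(f"iteration 1: {len(first.plan.jobs)} jobs planned, {done} succeeded")

    second = run_once(settings)
    print(f"iteration 2: {len(second.plan.jobs)} jobs planned, "
          f"{second.plan.skipped_existing} skipped because their output exists")

# Iteration 1 converts every .raw candidate the wildcard rule passes; the
# .wiff files and noise are blocked by default.  Iteration 2 plans nothing:
# each output already sits in its mgf/ subdirectory, so the loop has reached
# its fixed point and can safely run forever.
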