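"""Synthetic spool trees and mock converter executables.

Real deployments point the daemon at a shared directory that instruments
fill with vendor raw files following the facility layout
``project/area/instrument/user_date/filename``.  This module fabricates
such trees — including Waters-style candidates that are *directories*, a
share of non-conforming noise paths, and opaque random file contents — and
generates small self-contained mock converter executables honouring the
wrapper contract (``... <input> <output>`` as the final two arguments, exit
status 0 on success).  Together they make the whole system testable with no
instrument data and no vendor software.

Every mock additionally appends one line per invocation to a ``<script>.calls``
sidecar file, so tests can count how often a command actually ran.
"""
from __future__ import annotations

import random
import sys
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

_KEYWORDS = ("ETD", "CID", "HCD", "QC", "blank", "dda")


@dataclass(frozen=True)
class SpoolSpec:
    """Shape of a generated spool tree; identical (spec, seed) → identical tree.

    Defaults give 2 projects × 2 areas × 2 instruments × 2 users × 5 files
    = 80 conforming candidates plus 20 % noise: enough variety for the rule
    matcher, small enough for seconds-long tests.
    """

    n_projects: int = 2
    areas: tuple[str, ...] = ("Proteomics", "Metabolomics")
    instruments_per_area: int = 2
    users: tuple[str, ...] = ("jdoe", "asmith")
    files_per_leaf: int = 5
    date_range: tuple[date, date] = (date(2011, 1, 1), date(2011, 12, 31))
    extensions: tuple[tuple[str, float], ...] = ((".raw", 0.7), (".wiff", 0.3))
    noise_fraction: float = 0.2
    dir_fraction: float = 0.25  # share of conforming candidates that are folder bundles
    seed: int = 42


def _check(spec: SpoolSpec) -> None:
    counts = (spec.n_projects, spec.instruments_per_area, spec.files_per_leaf)
    if any(c < 0 for c in counts) or not 0 <= spec.noise_fraction <= 1:
        raise ValueError("counts must be >= 0 and noise_fraction within [0, 1]")


def _create(path: Path, rng: random.Random, as_dir: bool) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = rng.randbytes(rng.randint(16, 64))
    if as_dir:
        path.mkdir()
        (path / "_FUNC001.DAT").write_bytes(payload)
    else:
        path.write_bytes(payload)


def generate_spool_tree(
    spec: SpoolSpec, dest: str | Path, manifest_path: str | Path | None = None
) -> list[str]:
    """Create a spool tree under ``dest`` and return the manifest of relative
    paths (conforming candidates first, then noise).  Refuses a non-empty
    destination rather than silently overwriting.  When ``manifest_path`` is
    given the manifest is also written there, one path per line."""
    _check(spec)
    dest = Path(dest)
    if dest.exists() and any(dest.iterdir()):
        raise FileExistsError(f"destination {dest} is not empty")
    dest.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    exts, weights = zip(*spec.extensions) if spec.extensions else ((), ())
    first, last = spec.date_range
    span = max(0, (last - first).days)
    manifest: list[str] = []
    for p in range(spec.n_projects):
        project = f"p{1000 + p}"
        for area in spec.areas:
            for i in range(spec.instruments_per_area):
                instrument = f"{area[:5].upper()}_{i + 1}"
                for user in spec.users:
                    day = first + timedelta(days=rng.randint(0, span))
                    leaf = f"{project}/{area}/{instrument}/{user}_{day:%Y%m%d}"
                    for n in range(spec.files_per_leaf):
                        ext = rng.choices(exts, weights)[0]
                        rel = f"{leaf}/sample{n + 1}_{rng.choice(_KEYWORDS)}{ext}"
                        _create(dest / rel, rng, rng.random() < spec.dir_fraction)
                        manifest.append(rel)
    for n in range(round(spec.noise_fraction * len(manifest))):
        # noise: stray files at the spool root, never matching the layout
        ext = rng.choices(exts, weights)[0] if n % 2 == 0 and exts else ".txt"
        rel = f"stray_{n}{ext}"
        _create(dest / rel, rng, as_dir=False)
        manifest.append(rel)
    if manifest_path is not None:
        Path(manifest_path).write_text("".join(p + "\n" for p in manifest), encoding="utf-8")
    return manifest


_MOCK_BODIES = {
    "copy": "_copy(inp, out)",
    "fail": "sys.exit(1)",
    "slow": "time.sleep(0.5); _copy(inp, out)",
    "partial": 'pathlib.Path(out).write_bytes(b"partial"); sys.exit(1)',
}

_MOCK_TEMPLATE = """\
#!{python}
import pathlib, shutil, sys, time

def _copy(src, dst):
    if pathlib.Path(src).is_dir():
        shutil.copytree(src, dst)
    else:
        shutil.copy(src, dst)

inp, out = sys.argv[-2], sys.argv[-1]
with open(__file__ + ".calls", "a") as calls:
    calls.write(inp + "\\n")
{body}
"""


def make_mock_converter(kind: str, dest: str | Path) -> Path:
    """Emit an executable mock converter script of the given kind.

    ``copy`` copies input to output and exits 0; ``fail`` writes nothing and
    exits 1; ``slow`` sleeps half a second before copying; ``partial``
    writes to the handed output name and *then* exits 1, probing that the
    executor's temp-rename protocol leaves no final output behind.
    """
    if kind not in _MOCK_BODIES:
        raise ValueError(f"unsupported mock converter kind {kind!r}")
    script = Path(dest) / f"mock_{kind}.py"
    script.write_text(
        _MOCK_TEMPLATE.format(python=sys.executable, body=_MOCK_BODIES[kind]),
        encoding="utf-8",
    )
    script.chmod(script.stat().st_mode | 0o755)
    return script


def call_count(script: str | Path) -> int:
    """Number of times a generated mock converter was invoked."""
    sidecar = Path(f"{script}.calls")
    return len(sidecar.read_text(encoding="utf-8").splitlines()) if sidecar.exists() else 0
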