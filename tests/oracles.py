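"""Independent brute-force oracles and random scenario generation.

Everything here deliberately re-derives results from first principles —
naive path splitting, a full recursive walk filtered by suffix, a plain
double loop over candidates × rules — so that agreement with the package is
evidence, not tautology.
"""
from __future__ import annotations

import os
import random
import re
from datetime import date, datetime, timedelta
from pathlib import Path

from spoolconvert import Config, ConverterSpec, FilterRule

AREAS = ("Proteomics", "Metabolomics")
INSTRUMENTS = ("VELOS_1", "QTOF_2")
USERS = ("jdoe", "asmith", "blee")
EXTENSIONS = (".raw", ".wiff", ".mgf", ".txt")
PATTERNS = ("ETD", r"sample\d", "p1000.*ETD", "QTOF")


def naive_fields(rel: str) -> dict:
    """Second, independent split of the facility path convention."""
    pieces = rel.split("/")
    out = {"project": None, "area": None, "instrument": None, "user": None, "date": None}
    if len(pieces) >= 5:
        out["project"], out["area"], out["instrument"] = pieces[0], pieces[1], pieces[2]
        user_date = pieces[3]
        if "_" in user_date:
            idx = user_date.rindex("_")
            out["user"] = user_date[:idx]
            try:
                out["date"] = datetime.strptime(user_date[idx + 1 :], "%Y%m%d").date()
            except ValueError:
                pass
        else:
            out["user"] = user_date
    else:
        for key, piece in zip(("project", "area", "instrument"), pieces[:-1]):
            out[key] = piece
    return out


def naive_walk(root: Path, config: Config) -> list[str]:
    """All relative paths (files only) whose name ends with a known input extension."""
    exts = [c.from_file_ext for c in config.converters if c.from_file_ext]
    found = []
    for dirpath, _dirs, files in os.walk(root):
        for name in files:
            if any(name.endswith(e) for e in exts):
                rel = os.path.relpath(os.path.join(dirpath, name), root).replace(os.sep, "/")
                found.append(rel)
    return sorted(found)


def naive_match(rel: str, rule: FilterRule, conv: ConverterSpec) -> bool:
    if not rel.split("/")[-1].endswith(conv.from_file_ext):
        return False
    meta = naive_fields(rel)
    if rule.project is not None and meta["project"] != rule.project:
        return False
    if rule.area is not None and meta["area"] != rule.area:
        return False
    if rule.instrument is not None and meta["instrument"] != rule.instrument:
        return False
    if rule.user is not None and meta["user"] != rule.user:
        return False
    if rule.date_begin is not None or rule.date_end is not None:
        if meta["date"] is None:
            return False
        if rule.date_begin is not None and meta["date"] < rule.date_begin:
            return False
        if rule.date_end is not None and meta["date"] > rule.date_end:
            return False
    if rule.pattern is not None and re.search(rule.pattern, rel) is None:
        return False
    return True


def naive_output(abs_input: str, conv: ConverterSpec) -> str:
    head, name = os.path.split(abs_input)
    stem = name[: len(name) - len(conv.from_file_ext)]
    if conv.converter_dir:
        head = os.path.join(head, conv.converter_dir)
    return os.path.join(head, stem + conv.to_file_ext)


def brute_force_plan(
    root: Path,
    config: Config,
    local_hostname: str | None,
    ledger_pairs: set[tuple[str, str]],
) -> tuple[set[tuple[str, str, str, int]], tuple[int, int, int]]:
    """Expected jobs {(input, converter_id, output, rule_index)} and the
    (existing, errored, foreign) skip counts, from a plain double loop."""
    by_id = {c.converter_id: c for c in config.converters}
    matched: dict[tuple[str, str], int] = {}
    for rel in naive_walk(root, config):
        for index, rule in enumerate(config.rules):
            conv = by_id[rule.converter_id]
            if naive_match(rel, rule, conv):
                key = (str(root / rel), conv.converter_id)
                if key not in matched or index < matched[key]:
                    matched[key] = index
    jobs, existing, errored, foreign = set(), 0, 0, 0
    for (abs_input, cid), index in matched.items():
        conv = by_id[cid]
        if (abs_input, cid) in ledger_pairs:
            errored += 1
        elif os.path.exists(naive_output(abs_input, conv)):
            existing += 1
        elif (
            local_hostname is not None
            and conv.hostname
            and conv.hostname.split(".")[0].lower() != local_hostname.split(".")[0].lower()
        ):
            foreign += 1
        else:
            jobs.add((abs_input, cid, naive_output(abs_input, conv), index))
    return jobs, (existing, errored, foreign)


def random_config(rng: random.Random) -> Config:
    converters = []
    for n in range(rng.randint(1, 3)):
        from_ext = rng.choice(EXTENSIONS)
        to_ext = rng.choice(EXTENSIONS)
        conv_dir = rng.choice(("mgf", "out", ""))
        if not conv_dir and to_ext == from_ext:
            conv_dir = "out"
        converters.append(
            ConverterSpec(
                converter_id=f"c{n}",
                converter_cmd="/bin/true",
                converter_dir=conv_dir,
                converter_options="",
                from_file_ext=from_ext,
                to_file_ext=to_ext,
                hostname=rng.choice(("", "hostA", "hostB")),
            )
        )
    rules = []
    for _ in range(rng.randint(0, 4)):
        cid = rng.choice(converters).converter_id
        fields = {}
        if rng.random() < 0.4:
            fields["project"] = rng.choice(("p1000", "p1001", "p9999"))
        if rng.random() < 0.3:
            fields["area"] = rng.choice(AREAS)
        if rng.random() < 0.3:
            fields["instrument"] = rng.choice(INSTRUMENTS)
        if rng.random() < 0.3:
            fields["user"] = rng.choice(USERS)
        if rng.random() < 0.3:
            begin = date(2011, 1, 1) + timedelta(days=rng.randint(0, 300))
            fields["date_begin"] = begin
            fields["date_end"] = begin + timedelta(days=rng.randint(0, 120))
        if rng.random() < 0.4:
            fields["pattern"] = rng.choice(PATTERNS)
        rules.append(FilterRule(converter_id=cid, **fields))
    return Config(tuple(converters), tuple(rules))


def random_tree(rng: random.Random, root: Path) -> list[str]:
    """A small random spool tree of plain files: conforming paths plus noise."""
    rels = set()
    for _ in range(rng.randint(3, 12)):
        day = date(2011, 1, 1) + timedelta(days=rng.randint(0, 364))
        rels.add(
            f"p{rng.randint(1000, 1002)}/{rng.choice(AREAS)}/{rng.choice(INSTRUMENTS)}/"
            f"{rng.choice(USERS)}_{day:%Y%m%d}/sample{rng.randint(1, 4)}"
            f"_{rng.choice(('ETD', 'CID'))}{rng.choice(EXTENSIONS)}"
        )
    for n in range(rng.randint(0, 3)):
        rels.add(rng.choice((f"stray_{n}{rng.choice(EXTENSIONS)}", f"odd/deep_{n}.raw")))
    for rel in rels:
        path = root / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(b"x")
    return sorted(rels)


def random_scenario(
    rng: random.Random, root: Path
) -> tuple[Config, set[tuple[str, str]], str | None]:
    """Create a random (tree, config) instance with some outputs pre-existing
    and some (input, converter) pairs pre-failed; returns the ledger pairs and
    the local hostname to plan for."""
    root.mkdir(parents=True, exist_ok=True)
    random_tree(rng, root)
    config = random_config(rng)
    by_id = {c.converter_id: c for c in config.converters}
    pairs = [
        (str(root / rel), rule.converter_id)
        for rel in naive_walk(root, config)
        for rule in config.rules
        if naive_match(rel, rule, by_id[rule.converter_id])
    ]
    ledger_pairs = {p for p in pairs if rng.random() < 0.2}
    for abs_input, cid in pairs:
        if rng.random() < 0.2:
            out = Path(naive_output(abs_input, by_id[cid]))
            out.parent.mkdir(parents=True, exist_ok=True)
            out.touch()
    return config, ledger_pairs, rng.choice(("hostA", "hostB", None))
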