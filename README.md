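# spoolconvert

A rule-based, idempotent file-conversion daemon for shared spool
directories, aimed at mass-spectrometry core facilities (and anyone else
who needs "watch this tree, run that command on matching files, forever").

Instruments deposit proprietary raw files — Thermo `.raw`, Sciex `.wiff`,
Waters `.raw` *folders* — on shared storage far faster than anyone converts
them by hand, and each lab wants different converters and options (peak
picking, ETD vs CID runs, re-conversion with new tool versions).
`spoolconvert` reduces all of that to one XML file and one loop.

## How it works

The engine borrows its semantics from stateful packet filters: candidate
files are *blocked* by default, and declarative rules *pass* matching files
to a converter. Every iteration performs four steps:

1. **parse** the XML configuration (converters + rules) — re-read every
   iteration, so edits are hot;
2. **crawl** the spool root for entries named with a configured input
   extension, parsing the facility convention
   `project/area/instrument/user_date/filename` into path metadata;
3. **match** each candidate against every rule (exact filters on project /
   area / instrument / user, an inclusive date window, and an unanchored
   regular-expression search over the relative path; all present filters
   are conjunctive, and *all* matching rules fire);
4. **execute** the surviving jobs on a bounded worker pool, appending one
   record per job to a central log.

Three checks make the loop safe to run forever on any number of hosts:

- **idempotency** — a job is skipped if its output
  (`dirname(input)/converterDir/stem + toFileExt`) already exists; outputs
  are written to a temporary name and renamed only on success, so a partial
  file never masquerades as done;
- **error exclusion** — an (input, converter) pair whose last attempt
  failed is skipped in later iterations, so a corrupt file is tried exactly
  once; the ledger is derived purely from the central log;
- **host partitioning** — each converter names the host it runs on, so
  concurrent daemons on different machines divide the work with no locking.

Because converter outputs are themselves crawled, multi-level workflows
(`.raw → .mgf → .txt`) emerge with no extra machinery: an L-stage chain
converges in L iterations to a zero-job fixed point.

## Worked example

```sh
python examples/quickstart.py
```

```
spool tree: 96 entries, e.g. p1000/Proteomics/PROTE_1/jdoe_20110310/sample1_ETD.raw
iteration 1: 62 jobs planned, 62 succeeded
iteration 2: 0 jobs planned, 62 skipped because their output exists
```

The generated spool holds 96 entries (80 conforming candidates plus noise);
the wildcard `.raw` rule passes 62 of them (the `.wiff` files and noise are
blocked by default), a mock converter copies each to `mgf/<stem>.mgf`, and
the second iteration plans nothing — the fixed point that lets the daemon
loop indefinitely. `examples/two_stage_workflow.py` shows a two-stage chain
converging the same way (`{'A': 8}`, then `{'B': 2}`, then `{}`).

The same run from a shell:

```sh
spoolconvert validate --config fcc.xml
spoolconvert run --config fcc.xml --root /srv/spool --loop --interval 30
spoolconvert add-rule --config fcc.xml --converter-id 28 --project p1000 --pattern ETD
spoolconvert status --log /srv/spool/conversion.log
```

A minimal configuration:

```xml
<fccConfiguration>
  <converterList>
    <converter converterID="28" converterDir="mgf" converterCmd="/opt/bin/convert"
               converterOptions='--filter "peakPicking true 2-"'
               fromFileExt=".raw" toFileExt=".mgf" hostname="srv-1"/>
  </converterList>
  <rulesList>
    <rule converterID="28" project="p1000" keyword=".*ETD.*"/>
  </rulesList>
</fccConfiguration>
```

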