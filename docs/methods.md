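# Methods

## The processing model

`spoolconvert` treats conversion scheduling as a filtering problem in the
style of a stateful packet filter. The "packets" are candidate files on a
shared spool; the rule set decides which candidates *pass* to which
converter; everything else is *blocked*. Each daemon iteration is a pure
function of two pieces of state — the file tree and the central log — which
makes the system crash-only: killing it between iterations loses nothing,
and restarting it recomputes exactly the pending work.

An iteration runs parse → crawl → match → execute:

- **Parse.** The XML configuration holds converter bindings
  (`converterID`, `converterDir`, `converterCmd`, `converterOptions`,
  `fromFileExt`, `toFileExt`, `hostname`) and rules
  (`converterID`, `project`, `omics`, `instrument`, `user`, `beginDate`,
  `endDate`, `keyword`). Validation enforces: non-empty unique converter
  ids, extensions starting with `.`, a single-component output directory,
  output ≠ input, resolvable rule references, ordered date windows, and
  compilable patterns. Unknown attributes warn rather than fail so configs
  written by newer tools keep working. An absent and an empty rule
  attribute are both wildcards, tolerating hand-edited files.
- **Crawl.** Any entry — file *or* directory, since Waters raw data is a
  folder — whose name ends with a configured input extension is a
  candidate. Directory candidates are opaque bundles and are not descended
  into. Paths are interpreted against the layout
  `project/area/instrument/user_date/filename`; only the `user_date`
  component is split, on its last underscore, so instrument names may
  contain underscores. The layout is a convention, not a constraint: the
  parser is a pluggable argument to `crawl`, and non-conforming paths
  still yield (partial) metadata with `conforming=False` rather than an
  error.
- **Match.** All present rule filters are conjunctive. String filters are
  exact; dates are inclusive calendar-day bounds; `keyword` is an
  unanchored regex *search* over the relative path, so filename keywords
  behave as substrings. All matching rules fire (facilities layer
  instrument-wide standard rules and project-specific rules over the same
  files); duplicate (input, converter) matches collapse to one job keeping
  the lowest rule index. Skip checks apply in a fixed precedence — error
  ledger, then output-exists, then foreign host — so the skip counters are
  well defined; the ordering puts the cheapest, most conservative check
  first.
- **Execute.** Jobs run as external processes on a bounded thread pool
  (the workers only wait on subprocesses, so threads provide the same
  bounded parallelism as a process pool with simpler cross-platform
  behaviour). The argv is the converter command, the shell-style-tokenized
  option string (double-quoted groups survive as single tokens), the input
  path and the output path — no shell ever interprets it. The converter is
  handed a temporary output name (`<output>.part`); the executor renames it
  to the final path only when the process exits 0 and the temporary exists,
  and deletes it otherwise. This keeps "output exists" a safe idempotency
  predicate. Wrappers whose tools dictate their own output names must place
  the final artifact at the handed path — correctness inside the conversion
  is the wrapper's responsibility.

## State: the central log and the error ledger

Every job appends one tab-separated record (timestamp, host, converter id,
input, output, status, return code, duration; separators escaped) under a
lock, so records never interleave on one host. The error ledger is not a
file of its own: it is reconstructed each iteration by replaying the log —
a failure inserts its (input, converter) pair, a later success removes it.
Retrying therefore means either truncating the log or running one iteration
with `--retry-errors`, which ignores the ledger. Line atomicity is
guaranteed per host only; simultaneous multi-host appends on a network
share are assumed to be line-atomic by the filesystem, which SMB does not
strictly promise.

## Defaults and parameters

| parameter | default | rationale |
|---|---|---|
| `min_age_seconds` | 300 | instruments push files over the network; a five-minute age gate avoids converting half-copied files |
| `pool_size` | logical CPU count | converters are CPU-bound (peak picking, deconvolution); full utilization is the point |
| `loop_interval_seconds` | 30 | re-crawling immediately hot-spins on an empty spool; 30 s is negligible against multi-minute conversions |
| hostname match | unqualified, case-insensitive | DNS names are case-insensitive; short vs. fully-qualified names should not split a host against itself |
| converter `hostname` empty | runs on any host | convenient for single-host setups; explicit hostnames restore strict partitioning |
| date serialization | `YYYYMMDD` | sortable, unambiguous, matches directory-name usage |

Re-conversion with a new converter version is modelled as a *new* converter
entry with a distinct `converterDir` — the existence-only skip rule makes
version comparison unnecessary and keeps old and new outputs side by side.

On a transient configuration parse failure the loop keeps the previous good
configuration and logs a warning, trading strictness for availability; a
failure on the very first iteration still aborts, since there is nothing to
fall back to.

## The synthetic fixtures

`SpoolSpec`/`generate_spool_tree` fabricate spool trees following the
facility convention: by default 2 projects × 2 areas × 2 instruments × 2
users × 5 files = 80 conforming candidates, 20 % additional non-conforming
noise at the spool root, a 70/30 mix of `.raw`/`.wiff` names, 25 % of
candidates as Waters-style directory bundles, and opaque random bytes as
content. Identical (spec, seed) pairs produce identical manifests. Mock
converters are generated Python scripts honouring the wrapper contract
(`<input> <output>` as the final arguments, exit 0 on success) in four
flavours — `copy`, `fail`, `slow`, `partial` — and count their invocations
in a sidecar file so tests can verify the single-execution guarantee.

What the fixtures deliberately do **not** emulate: real vendor binary
formats (the engine never reads file contents, only paths), converter
runtimes of hours, network filesystem latency and permission semantics, or
clock skew between hosts. Passing tests therefore demonstrate the
scheduling logic — matching, idempotency, error exclusion, partitioning,
convergence — not throughput or robustness of any real converter.

## Verification

The test suite checks each operation against independent oracles: a second,
separately written path-convention parser; a naive full recursive walk
filtered by suffix; a brute-force candidates × rules double loop with naive
per-field checks (run over randomized tree/config/ledger instances); an
independent shell tokenizer; and a replay oracle for the ledger. System
properties — pool-size independence, host-partition tiling, the idempotent
fixed point, two-stage convergence, hot reload, single execution of failing
inputs — run end to end on generated fixtures. `scripts/acceptance.py`
re-measures all of these from scratch with fresh trees (100 oracle
instances, 100 round-tripped configs, the 80-file default tree for the
idempotency check, a reduced 16-file tree for the three-pool comparison to
keep three full executions brief) and writes the results as JSON.

## Limitations

- No OS file-notification service is used (they are OS-specific); the loop
  re-crawls, so latency is bounded by crawl time plus the loop interval.
- No cross-host locking exists; correctness across hosts relies entirely on
  converters being partitioned by hostname.
- One failure permanently excludes an (input, converter) pair until an
  operator intervenes; there is no automatic retry or backoff.
- Suffix matching is by name only; companion files (e.g. `.wiff.scan`) are
  not special-cased.
- The spool is never cleaned up by the daemon; an external process should
  prune it to keep crawl times bounded.
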