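# Methods

## Model

A workflow is a finite set of tasks with explicit dependency declarations;
the task-level dependency graph must be acyclic. Each task references one
module (a typed wrapper around a single command) and optionally one process
block. Scheduling operates on *subtasks*: a task without a block owns the
single reserved subtask index 0; a task with a block owns one subtask per
block instance, indexed 1..N in instance order.

Every subtask moves through a fixed lifecycle:

```
PENDING → READY → RUNNING → SUCCEEDED
            ├→ HELD_RESOURCE   → READY   (slot freed or hold released)
            ├→ HELD_CHECKPOINT → READY   (checkpoint released)
            ├→ SUCCEEDED                 (journal replay)
            └← FAILED_AWAITING_USER ← RUNNING
                 ├→ READY  (restart / modify+restart, attempt+1)
                 ├→ IGNORED
                 └→ RESOLVED_MANUAL (user-entered return values)
```

No other edges exist; `apply_transition` rejects anything else. EXCLUDED is
assigned at startup to tasks outside the active scope. A subtask becomes
launchable when (a) every task-level dependency is *fully* successful (all
subtasks SUCCEEDED/RESOLVED_MANUAL, or the dependency is outside the scope),
(b) every `separate` dependency has the index-matched upstream subtask
successful, (c) no upstream checkpoint is unreleased, and (d) the per-task
`maxRunning` cap leaves room. Per-executor slot caps are enforced by the
executor itself at launch time.

Failure handling is deliberately non-halting: a failed subtask blocks only
its forward dependency cone, everything else continues, and the failure waits
for one of four user actions (restart, modify parameters + restart, ignore,
resolve manually). Ignoring a failure permanently blocks its dependents and
the run then ends normally with a non-success summary; manual resolution
supplies the return values downstream process-input blocks would have read.
Verdicts on finished commands combine the exit code (zero = success) with
ordered user-declared checkers; only error votes (or a nonzero exit) can
produce FAILURE, so a success checker can corroborate but never veto — and
when success and error checkers disagree the subtask counts as failed.

Process-input expansion is deferred and, for `separate` dependencies,
incremental: subtask *B_x* is created the moment upstream *A_x* succeeds,
which is what enables per-sample pipelining. A join over multiple
dependencies requires `compareByIndex="true"` and merges return maps at equal
subtask indices; conflicting values for the same key are an error.

## Determinism and the virtual executor

The dialect makes no ordering promise, but this engine launches launchable
subtasks in ascending (task id, subtask index) order and assigns virtual
hosts lowest-free-index first, so that a given workflow plus a given virtual
configuration yields a byte-identical execution trace. That determinism is an
implementation choice for testability, not a semantic guarantee — workflows
must not rely on sibling ordering. Folder blocks sort instances
lexicographically by absolute path for the same reason.

The virtual executor is a discrete-event simulator: each launch occupies one
slot on a simulated host for a scripted duration (default 1.0 time units) and
finishes with a scripted exit code and return values. It backs `--dry-run`
(which therefore spawns no child process, and synthesizes stand-in values for
declared return parameters so input blocks still expand) and all trace-level
tests: barriers, pipelining, concurrency caps, checkpoint and resume
behavior, and slave-mode affinity, where a host constraint pins
dependency-connected subtasks to one host. SSH and cluster executor types
parse and register but launch refuses with "not configured"; real remote
execution is out of scope for this build.

## Interfaces and conventions

* Module descriptors: one `<name>.module.xml` per module folder; argv is
  rendered GNU-style, `--name value` per occurrence in declaration order,
  bare `--name` for set flags. Unassigned optional parameters render their
  default or are omitted. The rendering is a pure function of (descriptor,
  assignment map).
* Return values: a child process writes `key<TAB>value` lines to the file
  named by `$WATCHDOG_RETURN_FILE`; values type-check against the module's
  declared return parameters.
* Resume journal: append-only TSV of (task id, subtask index, sha-256 of the
  resolved argv, state, returns as JSON). Only SUCCEEDED entries with a
  matching argv hash are replayed, so any parameter edit forces
  re-execution.
* Constants are `${NAME}` with `NAME` matching `[A-Za-z_][A-Za-z0-9_]*`,
  expanded before scheduling with a recursion bound of 10 to catch
  self-reference. Instance placeholders (`{}`, `[k]`, `{$var}`) are expanded
  per subtask; `[k]` strips the last k dot-suffixes of the file name and
  requires at least k+1 dot-separated parts.
* Task actions run on the local file system only: `create` makes a directory
  when the path ends in `/`, else an empty file; `before` failures fail the
  subtask (reported as exit −1), `after_*` failures are logged.
* Scope filters: `--start T` keeps T and its dependency descendants,
  `--stop T` keeps T and its ancestors, minus excludes plus includes;
  dependencies on out-of-scope tasks count as satisfied.
* Exit status: 0 all active subtasks terminal-successful; 1 completed with
  failed/ignored/blocked subtasks; 2 invalid workflow or command line.

## Numerical and degenerate-input choices

Sequence blocks include the end bound when hit within 1e-9 of an exact step
multiple; integral (start, end, step) render without a decimal point so
values compose into file names. A folder or table block matching zero
instances is a warning, not an error: the task vacuously succeeds with no
subtasks. An empty workflow runs to an empty trace and success. Unreleased
checkpoints in a headless run raise a deadlock report listing the blocked
subtasks rather than hanging; the same detector flags any quiescent state
with non-terminal subtasks that is not explained by a pending user action or
an ignored upstream failure.

## Synthetic data

The bundled generators are deliberately minimal stand-ins for sequencing
data. `make_toy_fastq` writes gzipped 4-line-per-record FASTQ with uniform
random 50-nt sequences and arbitrary quality letters — no quality model, no
adapter structure, no biological signal; `make_log_folder` writes small
random text logs. They exist to exercise the engine (file counts, caps,
dependency shapes, byte-level determinism under a seed), so passing tests
demonstrate scheduling and recovery semantics, not the correctness of any
biological analysis. The bundled extraction pipeline defaults to 2 samples ×
100 reads, a size chosen so a full local run completes in seconds; read
counts are parameters, not claims.

## Design choices made where the design was open

* How a module's command receives parameter values is a convention of this
  engine (argv pairs, not environment or config files), as is the return-file
  mechanism via `WATCHDOG_RETURN_FILE`.
* "Modify and restart" re-renders the whole argv from the edited assignment
  map rather than patching the previous command.
* Checkers are looked up in a name→factory registry (`stderr_pattern`,
  `file_exists`, `min_file_size` ship built in) instead of loading compiled
  code from disk; workflows carry the registry name and typed constructor
  arguments.
* Notification is structured log events at failure (always) and success
  (debug) rather than email; the status/action HTTP endpoint replaces a
  browser UI while keeping all four recovery actions reachable headlessly.
* Block types and executor types are plugin registries keyed by XML element
  and type name, so new kinds can be added without touching engine code.

## Known limitations

No priorities, preemption, or wall-clock/memory quota enforcement; no remote
file systems (task actions are local-only); no recursive folder scanning or
regex file patterns; no XML namespaces or XInclude; the virtual executor
models durations and slots but not contention or failures beyond scripted
exit codes. Trace timestamps from the local executor are wall-clock and not
reproducible across runs — determinism guarantees apply to the virtual
executor only.
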