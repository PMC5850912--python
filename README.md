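# shepherd

A workflow management engine for bioinformatics-style command-line pipelines,
built for analyses that apply the same mutually dependent steps to many
samples, conditions and replicates.

High-throughput experiments (RNA-seq and friends) are analyzed as a chain of
programs — quality control, mapping, counting, statistics — repeated per
replicate. `shepherd` separates the three concerns such an analysis has:

* **Modules** wrap one command-line program each, declaring its parameters
  (name, type, valid range, occurrence counts) and optional *return
  parameters* in a small XML descriptor. Any program goes; modules are shared
  by copying their folder.
* **Workflows** (an XML dialect) wire modules into *tasks* with explicit
  task- or subtask-level dependencies, constants, per-task environment,
  stream redirects, checkpoints, error checkers, and executor assignments.
* The **engine** expands tasks into subtasks via *process blocks*, schedules
  them under per-task and per-executor concurrency limits, judges every
  finished command (exit code plus ordered custom success/error checkers),
  and keeps going when something fails: only the failed subtask's dependency
  cone is blocked, and the failure can be repaired headlessly (restart,
  modify parameters and restart, ignore, or resolve manually with
  hand-entered return values).

### Process blocks

A process block turns one task declaration into one subtask per *instance*:

| block | instances | variables |
|---|---|---|
| `processSequence` | numeric for-loop `start..end` by `step` | one (`{}`) |
| `processFolder` | files matching a glob in a folder | one (`{}`, `[k]`) |
| `processTable` | rows of a TSV file | one per column (`{$col}`) |
| `processInput` | return values of upstream subtasks | one per return key |

In parameter templates, `{}` substitutes the instance value, `[k]` the file
name with its last *k* dot-suffixes stripped, and `{$var}` a named variable;
`${NAME}` references a workflow constant. Subtask-level (`separate`)
dependencies pipeline per instance: subtask *B_x* starts as soon as *A_x*
finished, before the rest of *A*.

Execution back-ends are pluggable. A real local executor (process pool with a
slot cap) and a deterministic virtual-time executor (used by `--dry-run` and
the test suite; it also honors slave-mode host affinity so dependent subtasks
share a host) ship working; SSH/cluster declarations parse but are interface
stubs. Runs are observable as an execution trace (JSON lines), a status table,
and a minimal HTTP status/action endpoint, and are resumable from an
append-only journal keyed by argv hash, so edited parameters force
re-execution.

## Worked example

Generate a bundled scenario — the basic extraction pipeline on two synthetic
gzipped FASTQ samples — and run it:

```bash
python -c "from shepherd.scenarios import ScenarioSpec, emit_scenario;
print(emit_scenario(ScenarioSpec('extract_pipeline', samples=2, seed=1), 'demo'))"
shepherd run demo/workflow.xml
```

The workflow decompresses each sample, extracts read headers (at most 4
simultaneous subtasks) and read sequences (at most 1) into separate files,
recompresses the results and merges them per sample. The run prints the final
status table:

```
  subtask  module             state                  att host     exit
----------------------------------------------------------------------
     1- 1  decompressTask     succeeded                1 local       0
     1- 2  decompressTask     succeeded                1 local       0
     2- 1  extractTask        succeeded                1 local       0
     2- 2  extractTask        succeeded                1 local       0
     3- 1  extractTask        succeeded                1 local       0
     3- 2  extractTask        succeeded                1 local       0
     4- 1  gzipTask           succeeded                1 local       0
     4- 2  gzipTask           succeeded                1 local       0
     5- 1  gzipTask           succeeded                1 local       0
     5- 2  gzipTask           succeeded                1 local       0
     6- 0  mergeTask          succeeded                1 local       0
counters: succeeded=11
```

and exits 0; `demo/out/` then holds `sample_01.merged.gz` and
`sample_02.merged.gz` (headers followed by sequences, 2 lines per read).
Subtask `6-0` is the merge task: tasks without a process block own the
reserved subtask index 0. Useful variations: `shepherd check` validates
without running; `--dry-run` simulates on the virtual executor; `--start`,
`--stop`, `--include`, `--exclude` scope the run; `--resume journal.tsv`
skips previously succeeded subtasks; `--status-port` serves the JSON
status/action endpoint; `shepherd scaffold-module` creates a new module
folder.

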