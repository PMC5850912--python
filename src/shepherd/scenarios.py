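"""Self-contained demonstration scenarios and synthetic test data.

Each scenario writes a runnable folder — workflow XML, module folders with
real POSIX shell scripts, and deterministic synthetic input data — exercising
one engine feature:

* ``sleep_constant``   — one sleep task parameterized through a constant.
* ``block_demo``       — sequence, folder and table process blocks side by side.
* ``compress_logs``    — per-file compression with a per-task concurrency cap of 2.
* ``task_barrier``     — a task gated on three upstream tasks (one with 3 subtasks).
* ``pipelined_pairs``  — subtask-level dependencies: B_x starts once A_x finished.
* ``parallel_hosts``   — a two-host virtual executor with slave-mode affinity.
* ``extract_pipeline`` — end-to-end FASTQ pipeline: decompress, extract read
  headers (cap 4) and sequences (cap 1) into separate files, recompress, merge.

Generation is a pure function of (scenario, parameters, seed): the same seed
always yields byte-identical files.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass
from pathlib import Path

from .exceptions import ShepherdError
from .modules import ParamDef, ReturnParamDef, scaffold_module
from .workflow import (
    DependencyDecl,
    ExecutorDecl,
    TaskAction,
    TaskSpec,
    WorkflowSpec,
    serialize_workflow,
)
from . import blocks

SCENARIOS = (
    "sleep_constant",
    "block_demo",
    "compress_logs",
    "task_barrier",
    "pipelined_pairs",
    "parallel_hosts",
    "extract_pipeline",
)


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    n_files: int = 5
    samples: int = 2
    reads_per_sample: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.scenario_id not in SCENARIOS:
            raise ShepherdError(f"unknown scenario {self.scenario_id!r}; "
                                f"known: {', '.join(SCENARIOS)}")


def make_log_folder(dir: str | Path, n: int, seed: int = 0) -> list[Path]:
    """Write n deterministic pseudo-random ``sample_XXX.log`` files."""
    folder = Path(dir)
    folder.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    out = []
    for i in range(1, n + 1):
        lines = [
            f"entry {rng.randrange(10**6)} level={rng.choice(['INFO', 'WARN'])}"
            for _ in range(rng.randint(3, 8))
        ]
        path = folder / f"sample_{i:03d}.log"
        path.write_text("\n".join(lines) + "\n")
        out.append(path)
    return out


def make_toy_fastq(dir: str | Path, samples: int, reads_per_sample: int,
                   seed: int = 0) -> list[Path]:
    """Write gzipped toy FASTQ files (4 lines per record), deterministic under seed."""
    folder = Path(dir)
    folder.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    out = []
    for s in range(1, samples + 1):
        records = []
        for r in range(1, reads_per_sample + 1):
            seq = "".join(rng.choice("ACGT") for _ in range(50))
            qual = "".join(rng.choice("FGHI") for _ in range(50))
            records.append(f"@sample{s:02d}.read{r}\n{seq}\n+\n{qual}\n")
        path = folder / f"sample_{s:02d}.fastq.gz"
        path.write_bytes(gzip.compress("".join(records).encode(), mtime=0))
        out.append(path)
    return out


def emit_scenario(spec: ScenarioSpec, outdir: str | Path) -> Path:
    """Write the scenario folder; returns the workflow XML path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    builder = {
        "sleep_constant": _sleep_constant,
        "block_demo": _block_demo,
        "compress_logs": _compress_logs,
        "task_barrier": _task_barrier,
        "pipelined_pairs": _pipelined_pairs,
        "parallel_hosts": _parallel_hosts,
        "extract_pipeline": _extract_pipeline,
    }[spec.scenario_id]
    wf = builder(spec, out)
    wf_path = out / "workflow.xml"
    wf_path.write_bytes(serialize_workflow(wf))
    return wf_path


# --------------------------------------------------------------------------- modules

def _module(out: Path, name: str, params, returns=(), body: str = ": # noop") -> None:
    moddir = out / "modules"
    if (moddir / name).exists():
        return
    scaffold_module(name, params, with_skeleton=True, dest_dir=moddir,
                    returns=returns, body=body)


def _file_param(name: str) -> ParamDef:
    return ParamDef(name, "file", required=True)


_RETURN_SELF = 'printf \'file\\t%s\\n\' "$output" > "$WATCHDOG_RETURN_FILE"'


# --------------------------------------------------------------------------- scenarios

def _sleep_constant(spec: ScenarioSpec, out: Path) -> WorkflowSpec:
    _module(out, "sleepTask",
            [ParamDef("wait", "integer", required=True, numeric_range=(0, 86400))],
            body='sleep "$wait"')
    return WorkflowSpec(
        constants=(("WAIT_TIME", "30"),),
        tasks=(
            TaskSpec(id=1, name="sleep", module_ref="sleepTask",
                     parameters=(("wait", "${WAIT_TIME}"),)),
        ),
    )


def _echo_module(out: Path) -> None:
    _module(out, "echoTask", [ParamDef("value", "string", required=True)],
            body='printf \'%s\\n\' "$value"')


def _block_demo(spec: ScenarioSpec, out: Path) -> WorkflowSpec:
    make_log_folder(out / "data", spec.n_files, spec.seed)
    (out / "data" / "samples.tsv").write_text(
        "name\ttype\nsample1\twildtype\nsample2\tknockout\n"
    )
    _echo_module(out)
    return WorkflowSpec(
        blocks=(
            blocks.SequenceBlock("num", 1, 9, 4),
            blocks.FolderBlock("logFiles", "data", "*.log"),
            blocks.TableBlock("samples", "data/samples.tsv"),
        ),
        tasks=(
            TaskSpec(id=1, name="seq_echo", module_ref="echoTask",
                     process_block_ref="num", parameters=(("value", "{}"),)),
            TaskSpec(id=2, name="log_echo", module_ref="echoTask",
                     process_block_ref="logFiles", parameters=(("value", "[1]"),)),
            TaskSpec(id=3, name="table_echo", module_ref="echoTask",
                     process_block_ref="samples",
                     parameters=(("value", "{$name}-{$type}"),)),
        ),
    )


def _compress_logs(spec: ScenarioSpec, out: Path) -> WorkflowSpec:
    make_log_folder(out / "data", spec.n_files, spec.seed)
    _module(out, "gzipTask", [_file_param("input"), _file_param("output")],
            returns=[ReturnParamDef("file")],
            body=f'gzip -c "$input" > "$output"\n{_RETURN_SELF}')
    return WorkflowSpec(
        executors=(ExecutorDecl(name="local", exec_type="local", max_slots=8,
                                default=True),),
        blocks=(blocks.FolderBlock("logFiles", "data", "*.log"),),
        tasks=(
            TaskSpec(id=1, name="compress", module_ref="gzipTask",
                     process_block_ref="logFiles", max_running=2,
                     parameters=(("input", "{}"), ("output", "out/[1].gz")),
                     task_actions=(TaskAction("before", "create", "out/"),)),
        ),
    )


def _noop_module(out: Path) -> None:
    _module(out, "noopTask", [], body=":")


def _task_barrier(spec: ScenarioSpec, out: Path) -> WorkflowSpec:
    _noop_module(out)
    _echo_module(out)
    return WorkflowSpec(
        blocks=(blocks.SequenceBlock("triple", 1, 3, 1),),
        tasks=(
            TaskSpec(id=1, name="A1", module_ref="noopTask"),
            TaskSpec(id=2, name="A2", module_ref="echoTask",
                     process_block_ref="triple", parameters=(("value", "{}"),)),
            TaskSpec(id=3, name="A3", module_ref="noopTask"),
            TaskSpec(id=4, name="B", module_ref="noopTask",
                     dependencies=(DependencyDecl("1"), DependencyDecl("2"),
                                   DependencyDecl("3"))),
        ),
    )


def _stage_module(out: Path) -> None:
    _module(out, "stageTask", [_file_param("input")],
            returns=[ReturnParamDef("file")],
            body='printf \'file\\t%s\\n\' "$input" > "$WATCHDOG_RETURN_FILE"')


def _pipelined_pairs(spec: ScenarioSpec, out: Path) -> WorkflowSpec:
    make_log_folder(out / "data", 3, spec.seed)
    _stage_module(out)
    return WorkflowSpec(
        executors=(ExecutorDecl(name="local", exec_type="local", max_slots=4,
                                default=True),),
        blocks=(
            blocks.FolderBlock("logFiles", "data", "*.log"),
            blocks.InputBlock("staged"),
        ),
        tasks=(
            TaskSpec(id=1, name="A", module_ref="stageTask",
                     process_block_ref="logFiles", max_running=1,
                     parameters=(("input", "{}"),)),
            TaskSpec(id=2, name="B", module_ref="stageTask",
                     process_block_ref="staged",
                     dependencies=(DependencyDecl("1", separate=True),),
                     parameters=(("input", "{$file}"),)),
        ),
    )


def _parallel_hosts(spec: ScenarioSpec, out: Path) -> WorkflowSpec:
    _echo_module(out)
    return WorkflowSpec(
        executors=(
            ExecutorDecl(name="cluster", exec_type="virtual", max_slots=2, default=True,
                         attributes=(("hosts", "2"), ("slotsPerHost", "1"),
                                     ("slave", "true"))),
        ),
        blocks=(blocks.SequenceBlock("pair", 1, 2, 1),),
        tasks=(
            TaskSpec(id=1, name="A", module_ref="echoTask", process_block_ref="pair",
                     executor_ref="cluster", parameters=(("value", "{}"),)),
            TaskSpec(id=2, name="B", module_ref="echoTask", process_block_ref="pair",
                     executor_ref="cluster",
                     dependencies=(DependencyDecl("1", separate=True),),
                     parameters=(("value", "{}"),)),
        ),
    )


_EXTRACT_BODY = """\
case "$mode" in
    headers)   awk 'NR % 4 == 1' "$input" > "$output" ;;
    sequences) awk 'NR % 4 == 2' "$input" > "$output" ;;
esac
""" + _RETURN_SELF

_MERGE_BODY = """\
for h in "$indir"/*.headers.gz; do
    base=$(basename "$h" .headers.gz)
    cat "$h" "$indir/$base.seqs.gz" > "$outdir/$base.merged.gz"
done
"""


def _extract_pipeline(spec: ScenarioSpec, out: Path) -> WorkflowSpec:
    """Decompress FASTQ, split headers/sequences, recompress, merge per sample.

    Sequence extraction is capped at 1 simultaneous subtask, header extraction
    at 4; every other stage pipelines per sample via subtask dependencies.
    """
    make_toy_fastq(out / "data", spec.samples, spec.reads_per_sample, spec.seed)
    _module(out, "decompressTask", [_file_param("input"), _file_param("output")],
            returns=[ReturnParamDef("file")],
            body=f'gzip -dc "$input" > "$output"\n{_RETURN_SELF}')
    _module(out, "extractTask",
            [_file_param("input"), _file_param("output"),
             ParamDef("mode", "enum", required=True,
                      enum_values=("headers", "sequences"))],
            returns=[ReturnParamDef("file")], body=_EXTRACT_BODY)
    _module(out, "gzipTask", [_file_param("input"), _file_param("output")],
            returns=[ReturnParamDef("file")],
            body=f'gzip -c "$input" > "$output"\n{_RETURN_SELF}')
    _module(out, "mergeTask",
            [ParamDef("indir", "folder", required=True),
             ParamDef("outdir", "folder", required=True)],
            body=_MERGE_BODY)
    dep = DependencyDecl
    return WorkflowSpec(
        executors=(ExecutorDecl(name="local", exec_type="local", max_slots=8,
                                default=True),),
        blocks=(
            blocks.FolderBlock("fastqFiles", "data", "*.fastq.gz"),
            blocks.InputBlock("decompressed1"),
            blocks.InputBlock("decompressed2"),
            blocks.InputBlock("headersOut"),
            blocks.InputBlock("seqsOut"),
        ),
        tasks=(
            TaskSpec(id=1, name="decompress", module_ref="decompressTask",
                     process_block_ref="fastqFiles",
                     parameters=(("input", "{}"), ("output", "work/[2].fastq")),
                     task_actions=(TaskAction("before", "create", "work/"),
                                   TaskAction("before", "create", "out/"))),
            TaskSpec(id=2, name="extractHeaders", module_ref="extractTask",
                     process_block_ref="decompressed1", max_running=4,
                     dependencies=(dep("1", separate=True),),
                     parameters=(("input", "{$file}"), ("output", "work/[1].headers"),
                                 ("mode", "headers"))),
            TaskSpec(id=3, name="extractSeqs", module_ref="extractTask",
                     process_block_ref="decompressed2", max_running=1,
                     dependencies=(dep("1", separate=True),),
                     parameters=(("input", "{$file}"), ("output", "work/[1].seqs"),
                                 ("mode", "sequences"))),
            TaskSpec(id=4, name="gzipHeaders", module_ref="gzipTask",
                     process_block_ref="headersOut",
                     dependencies=(dep("2", separate=True),),
                     parameters=(("input", "{$file}"), ("output", "out/[1].headers.gz"))),
            TaskSpec(id=5, name="gzipSeqs", module_ref="gzipTask",
                     process_block_ref="seqsOut",
                     dependencies=(dep("3", separate=True),),
                     parameters=(("input", "{$file}"), ("output", "out/[1].seqs.gz"))),
            TaskSpec(id=6, name="merge", module_ref="mergeTask",
                     dependencies=(dep("4"), dep("5")),
                     parameters=(("indir", "out"), ("outdir", "out"))),
        ),
    )
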