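"""Subtask lifecycle and the scheduling engine.

Tasks expand into subtasks (one per process-block instance; a task without a
block owns the single reserved subtask index 0).  The engine repeatedly
promotes subtasks whose dependencies are resolved, launches them on their
executor within per-task and per-executor concurrency limits, judges finished
commands, and applies lifecycle transitions until nothing is left to do.

Lifecycle::

    PENDING -> READY -> RUNNING -> SUCCEEDED
                 |          `----> FAILED_AWAITING_USER -> READY (restart)
                 |                                      -> IGNORED
                 |                                      -> RESOLVED_MANUAL
                 |-> HELD_RESOURCE  -> READY (slot freed / user release)
                 |-> HELD_CHECKPOINT-> READY (checkpoint released)
                 `-> SUCCEEDED (journal replay)

A failed subtask blocks only its dependency cone; everything else keeps
running.  Launch order among launchable subtasks is ascending
(task_id, subtask_index) so virtual-executor traces are reproducible — this
determinism is an implementation choice of this engine, not a semantic
guarantee of the workflow dialect.
"""

from __future__ import annotations

import hashlib
import json
import logging
import threading
import time as _time
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx

from . import blocks as _blocks
from .checks import Artifacts, judge_result, resolve_manually
from .exceptions import (
    DeadlockError,
    ExecutorError,
    SchedulerError,
    TaskActionError,
    TransitionError,
    WorkflowError,
)
from .executors import (
    CommandInvocation,
    VirtualClock,
    VirtualExecutor,
    VirtualExecutorConfig,
    apply_affinity,
    build_executor,
    run_task_actions,
)
from .modules import ModuleRegistry, render_command
from .workflow import WorkflowSpec, resolve_constants

logger = logging.getLogger(__name__)


class SubtaskState(Enum):
    PENDING = "PENDING"
    READY = "READY"
    HELD_RESOURCE = "HELD_RESOURCE"
    HELD_CHECKPOINT = "HELD_CHECKPOINT"
    RUNNING = "RUNNING"
    SUCCEEDED = "SUCCEEDED"
    FAILED_AWAITING_USER = "FAILED_AWAITING_USER"
    IGNORED = "IGNORED"
    RESOLVED_MANUAL = "RESOLVED_MANUAL"
    EXCLUDED = "EXCLUDED"


S = SubtaskState
TERMINAL_SUCCESS = {S.SUCCEEDED, S.RESOLVED_MANUAL}
TERMINAL = TERMINAL_SUCCESS | {S.IGNORED, S.EXCLUDED}

#: legal (state, event) -> new state
_TRANSITIONS: dict[tuple[SubtaskState, str], SubtaskState] = {
    (S.PENDING, "ready"): S.READY,
    (S.PENDING, "exclude"): S.EXCLUDED,
    (S.READY, "launch"): S.RUNNING,
    (S.READY, "hold_resource"): S.HELD_RESOURCE,
    (S.READY, "hold_checkpoint"): S.HELD_CHECKPOINT,
    (S.READY, "replay"): S.SUCCEEDED,
    (S.HELD_RESOURCE, "release"): S.READY,
    (S.HELD_CHECKPOINT, "release"): S.READY,
    (S.RUNNING, "succeed"): S.SUCCEEDED,
    (S.RUNNING, "fail"): S.FAILED_AWAITING_USER,
    (S.FAILED_AWAITING_USER, "user_restart"): S.READY,
    (S.FAILED_AWAITING_USER, "user_modify_restart"): S.READY,
    (S.FAILED_AWAITING_USER, "user_ignore"): S.IGNORED,
    (S.FAILED_AWAITING_USER, "user_resolve"): S.RESOLVED_MANUAL,
}


@dataclass
class SubtaskRecord:
    task_id: int
    subtask_index: int  # >= 1 for block instances, 0 for block-less tasks
    instance: _blocks.Instance | None = None
    state: SubtaskState = S.PENDING
    resolved_argv: tuple[str, ...] | None = None
    exit_code: int | None = None
    return_values: dict = field(default_factory=dict)
    attempt: int = 1
    host: str | None = None
    messages: list[str] = field(default_factory=list)
    param_overrides: tuple[tuple[str, str], ...] | None = None
    hold_released: bool = False
    stdout_path: str | None = None
    stderr_path: str | None = None
    return_file: str | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.task_id, self.subtask_index)

    def label(self) -> str:
        return f"{self.task_id}-{self.subtask_index}"


def apply_transition(record: SubtaskRecord, event: str, *, return_values: dict | None = None,
                     param_overrides=None) -> SubtaskRecord:
    """Apply one lifecycle event in place; raise on an illegal edge."""
    edge = (record.state, event)
    if edge not in _TRANSITIONS:
        raise TransitionError(
            f"subtask {record.label()}: event {event!r} illegal in state {record.state.name}"
        )
    new = _TRANSITIONS[edge]
    if event in ("user_restart", "user_modify_restart"):
        record.attempt += 1
        record.exit_code = None
        record.resolved_argv = None
        record.host = None
        if event == "user_modify_restart":
            record.param_overrides = param_overrides
    if event == "user_resolve":
        record.return_values = dict(return_values or {})
    if event in ("succeed", "replay") and return_values is not None:
        record.return_values = dict(return_values)
    record.state = new
    return record


# --------------------------------------------------------------------------- trace

@dataclass(frozen=True)
class TraceEvent:
    time: float
    task_id: int
    subtask_index: int
    transition: str
    host: str | None = None


class ExecutionTrace:
    """Ordered transition events; the primary observable of a run."""

    def __init__(self, events: Iterable[TraceEvent] = ()):
        self.events: list[TraceEvent] = list(events)

    def add(self, time: float, task_id: int, subtask_index: int, transition: str,
            host: str | None = None) -> None:
        if self.events and time < self.events[-1].time:
            time = self.events[-1].time  # clamp: times are non-decreasing
        self.events.append(TraceEvent(round(time, 9), task_id, subtask_index, transition, host))

    def by_transition(self, name: str) -> list[TraceEvent]:
        return [e for e in self.events if e.transition == name]

    def for_task(self, task_id: int) -> list[TraceEvent]:
        return [e for e in self.events if e.task_id == task_id]

    def first(self, task_id: int, subtask_index: int, transition: str) -> TraceEvent | None:
        for e in self.events:
            if (e.task_id, e.subtask_index, e.transition) == (task_id, subtask_index, transition):
                return e
        return None

    def max_concurrent_running(self, predicate: Callable[[TraceEvent], bool] | None = None) -> int:
        """Peak number of simultaneously RUNNING subtasks (optionally filtered)."""
        active: set[tuple[int, int]] = set()
        peak = 0
        for e in self.events:
            if predicate is not None and not predicate(e):
                continue
            key = (e.task_id, e.subtask_index)
            if e.transition == "running":
                active.add(key)
                peak = max(peak, len(active))
            elif e.transition in ("succeeded", "failed_awaiting_user"):
                active.discard(key)
        return peak

    def to_jsonl(self) -> str:
        return "".join(
            json.dumps(
                {"time": e.time, "task": e.task_id, "subtask": e.subtask_index,
                 "transition": e.transition, "host": e.host},
                sort_keys=True,
            ) + "\n"
            for e in self.events
        )

    @classmethod
    def from_jsonl(cls, text: str) -> "ExecutionTrace":
        events = []
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            events.append(TraceEvent(d["time"], d["task"], d["subtask"], d["transition"],
                                     d.get("host")))
        return cls(events)

    def __len__(self):
        return len(self.events)


# --------------------------------------------------------------------------- scope

@dataclass(frozen=True)
class ScopeFilter:
    start: str | None = None
    stop: str | None = None
    include: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()
    disable_checkpoints: bool = False


def build_graph(spec: WorkflowSpec) -> nx.DiGraph:
    """Task-level dependency graph: edge u -> v iff v depends on u."""
    g = nx.DiGraph()
    g.add_nodes_from(t.id for t in spec.tasks)
    for t in spec.tasks:
        for d in t.dependencies:
            u = spec.task_by_ref(d.target)
            g.add_edge(u.id, t.id, separate=d.separate)
    if not nx.is_directed_acyclic_graph(g):
        raise SchedulerError("task dependency graph contains a cycle")
    return g


def apply_scope(spec: WorkflowSpec, filter: ScopeFilter | None) -> set[int]:
    """Active task ids under -start/-stop/-include/-exclude semantics.

    Active = tasks between start and stop in the dependency partial order,
    minus excludes, plus includes.  Dependencies of active tasks on inactive
    ones count as satisfied.
    """
    all_ids = {t.id for t in spec.tasks}
    if filter is None:
        return all_ids
    g = build_graph(spec)
    active = set(all_ids)
    if filter.start is not None:
        s = spec.task_by_ref(filter.start).id
        active &= {s} | nx.descendants(g, s)
    if filter.stop is not None:
        p = spec.task_by_ref(filter.stop).id
        active &= {p} | nx.ancestors(g, p)
    include = {spec.task_by_ref(r).id for r in filter.include}
    exclude = {spec.task_by_ref(r).id for r in filter.exclude}
    if include & exclude:
        raise SchedulerError(f"include and exclude overlap: {sorted(include & exclude)}")
    return (active - exclude) | include


# --------------------------------------------------------------------------- resume journal

def _argv_hash(argv: Iterable[str]) -> str:
    return hashlib.sha256("\x00".join(argv).encode()).hexdigest()


class ResumeJournal:
    """Append-only TSV of (task_id, subtask_index, argv_hash, state, returns).

    A rerun replays entries recorded as SUCCEEDED with a matching argv hash,
    so editing a task's parameters forces re-execution.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.entries: dict[tuple[int, int, str], tuple[str, dict]] = {}
        if self.path.exists():
            for line in self.path.read_text().splitlines():
                if not line.strip():
                    continue
                tid, idx, ahash, state, returns = line.split("\t", 4)
                self.entries[(int(tid), int(idx), ahash)] = (state, json.loads(returns))

    def match_succeeded(self, task_id: int, idx: int, argv: Iterable[str]) -> dict | None:
        entry = self.entries.get((task_id, idx, _argv_hash(argv)))
        if entry and entry[0] == "SUCCEEDED":
            return entry[1]
        return None

    def record(self, record: SubtaskRecord) -> None:
        key = (record.task_id, record.subtask_index, _argv_hash(record.resolved_argv or ()))
        value = (record.state.name, dict(record.return_values))
        if self.entries.get(key) == value:
            return
        self.entries[key] = value
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "a") as fh:
            fh.write("\t".join([
                str(record.task_id), str(record.subtask_index), key[2],
                record.state.name, json.dumps(value[1], sort_keys=True),
            ]) + "\n")


# --------------------------------------------------------------------------- engine

class Engine:
    """Drives one workflow run: expansion, scheduling, judgment, recovery.

    Parameters
    ----------
    spec : parsed workflow (constants may be unresolved; resolved here).
    registry : module registry; the spec's own module folders are appended.
    executors : optional prebuilt name -> Executor map; otherwise built from
        the spec's declarations (all of them virtual when ``dry_run``).
    scope : -start/-stop/-include/-exclude/-disableCheckpoint filter.
    journal_path : resume journal; succeeded subtasks recorded there are
        replayed without execution on a rerun.
    virtual_config : scripted durations/exit codes/returns applied to every
        virtual executor built for this run.
    """

    def __init__(
        self,
        spec: WorkflowSpec,
        registry: ModuleRegistry,
        executors: Mapping[str, object] | None = None,
        scope: ScopeFilter | None = None,
        journal_path: str | Path | None = None,
        workdir: str | Path | None = None,
        dry_run: bool = False,
        virtual_config: VirtualExecutorConfig | None = None,
    ):
        self.spec = resolve_constants(spec)
        self.registry = registry
        for folder in self.spec.module_folders:
            p = Path(folder)
            if not p.is_absolute():
                p = Path(self.spec.base_dir) / p
            registry.add_search_path(p)
        self.scope = scope or ScopeFilter()
        self.graph = build_graph(self.spec)
        self.active = apply_scope(self.spec, scope)
        self.trace = ExecutionTrace()
        self.records: dict[tuple[int, int], SubtaskRecord] = {}
        self.released_checkpoints: set[int] = set()
        self.journal = ResumeJournal(journal_path) if journal_path else None
        self.scratch = Path(workdir) if workdir else Path(self.spec.base_dir) / ".shepherd"
        self.scratch.mkdir(parents=True, exist_ok=True)
        self.dry_run = dry_run
        self._lock = threading.RLock()
        self._actions: list[tuple] = []
        self._expanded: dict[int, bool] = {}
        self._input_blocks: dict[int, _blocks.InputBlock] = {}
        self._t0 = _time.monotonic()
        self.clock: VirtualClock | None = None
        self.executors = dict(executors) if executors else self._build_executors(virtual_config)
        if any(isinstance(e, VirtualExecutor) for e in self.executors.values()):
            clocks = {e.clock for e in self.executors.values() if isinstance(e, VirtualExecutor)}
            if len(clocks) > 1:
                raise SchedulerError("all virtual executors of one run must share a clock")
            self.clock = clocks.pop()
        self._init_records()

    # -- construction -------------------------------------------------------

    def _build_executors(self, virtual_config):
        clock = VirtualClock()
        out: dict[str, object] = {}
        decls = list(self.spec.executors)
        if not decls:
            from .workflow import ExecutorDecl
            decls = [ExecutorDecl(name="local", exec_type="local", max_slots=1, default=True)]
        for decl in decls:
            if self.dry_run or (virtual_config is not None and decl.exec_type in ("local", "virtual")):
                cfg = self._virtual_cfg_for(decl, virtual_config)
                out[decl.name] = VirtualExecutor(cfg, clock=clock, name=decl.name)
            else:
                out[decl.name] = build_executor(decl, clock=clock)
        return out

    @staticmethod
    def _virtual_cfg_for(decl, virtual_config) -> VirtualExecutorConfig:
        attrs = decl.attr_map
        hosts = int(attrs.get("hosts", "1"))
        slots = int(attrs.get("slotsPerHost", "0")) or max(1, decl.max_slots // hosts)
        slave = attrs.get("slave", "false").lower() in ("true", "1", "yes")
        base = virtual_config or VirtualExecutorConfig()
        return VirtualExecutorConfig(
            hosts=hosts,
            slots_per_host=slots,
            duration_of=dict(base.duration_of),
            exit_code_of=dict(base.exit_code_of),
            returns_of=dict(base.returns_of),
            default_duration=base.default_duration,
            slave_mode=slave or base.slave_mode,
        )

    def _init_records(self) -> None:
        for task in sorted(self.spec.tasks, key=lambda t: t.id):
            if task.id not in self.active:
                rec = SubtaskRecord(task.id, 0, state=S.EXCLUDED)
                self.records[rec.key] = rec
                self._expanded[task.id] = True
                self.trace.add(self.now(), task.id, 0, "excluded")
                continue
            if task.process_block_ref is None:
                self.records[(task.id, 0)] = SubtaskRecord(task.id, 0)
                self._expanded[task.id] = True
                continue
            decl = self.spec.block_by_name(task.process_block_ref)
            if isinstance(decl, _blocks.InputBlock):
                self._input_blocks[task.id] = decl
                self._expanded[task.id] = False
                continue
            decl = self._localize_block(decl)
            for inst in _blocks.expand_block(decl):
                rec = SubtaskRecord(task.id, inst.ordinal, instance=inst)
                self.records[rec.key] = rec
            self._expanded[task.id] = True

    def _localize_block(self, decl):
        """Resolve block file paths relative to the workflow directory."""
        base = Path(self.spec.base_dir)
        if isinstance(decl, _blocks.FolderBlock) and not Path(decl.folder).is_absolute():
            return replace(decl, folder=str(base / decl.folder))
        if isinstance(decl, _blocks.TableBlock) and not Path(decl.table).is_absolute():
            return replace(decl, table=str(base / decl.table))
        return decl

    # -- time ----------------------------------------------------------------

    def now(self) -> float:
        if self.clock is not None:
            return self.clock.time
        return round(_time.monotonic() - self._t0, 6)

    # -- dependency resolution ----------------------------------------------

    def _task_settled(self, task_id: int) -> bool:
        """All subtasks of a task exist and are terminal (any outcome)."""
        if not self._expanded.get(task_id, False):
            return False
        recs = [r for r in self.records.values() if r.task_id == task_id]
        return all(r.state in TERMINAL for r in recs)

    def _task_successful(self, task_id: int) -> bool:
        if not self._expanded.get(task_id, False):
            return False
        recs = [r for r in self.records.values() if r.task_id == task_id]
        return all(r.state in TERMINAL_SUCCESS | {S.EXCLUDED} for r in recs)

    def _dep_status(self, record: SubtaskRecord) -> str:
        """'ok' | 'wait' | 'blocked' for the record's dependencies."""
        task = self.spec.task_by_ref(record.task_id)
        status = "ok"
        for dep in task.dependencies:
            up = self.spec.task_by_ref(dep.target)
            if up.id not in self.active:
                continue
            if dep.separate:
                st = self._separate_dep_status(up.id, record.subtask_index)
            else:
                st = self._task_dep_status(up.id)
            if st == "blocked":
                return "blocked"
            if st == "wait":
                status = "wait"
        return status

    def _task_dep_status(self, up_id: int) -> str:
        if self._task_successful(up_id):
            return "ok"
        if self._task_settled(up_id):
            return "blocked"  # contains an IGNORED subtask
        return "wait"

    def _separate_dep_status(self, up_id: int, idx: int) -> str:
        match_idx = 0 if (up_id, 0) in self.records else idx
        rec = self.records.get((up_id, match_idx))
        if rec is None:
            return "blocked" if self._task_settled(up_id) else "wait"
        if rec.state in TERMINAL_SUCCESS or rec.state is S.EXCLUDED:
            return "ok"
        if rec.state is S.IGNORED:
            return "blocked"
        return "wait"

    def _checkpoint_holds(self, record: SubtaskRecord) -> bool:
        if self.scope.disable_checkpoints:
            return False
        task = self.spec.task_by_ref(record.task_id)
        for dep in task.dependencies:
            up = self.spec.task_by_ref(dep.target)
            if (up.checkpoint and up.id in self.active
                    and up.id not in self.released_checkpoints):
                return True
        return False

    # -- input-block expansion ------------------------------------------------

    def _expand_inputs(self) -> bool:
        progressed = False
        for tid, block in sorted(self._input_blocks.items()):
            if self._expanded.get(tid):
                continue
            task = self.spec.task_by_ref(tid)
            deps = [d for d in task.dependencies
                    if self.spec.task_by_ref(d.target).id in self.active]
            if not deps:
                self._expanded[tid] = True  # nothing to derive instances from
                continue
            if len(deps) > 1 and not block.compare_by_index:
                raise SchedulerError(
                    f"task {tid}: input block over multiple dependencies requires "
                    "compareByIndex='true'"
                )
            if len(deps) == 1 and deps[0].separate:
                progressed |= self._expand_input_incremental(tid, block, deps[0])
            elif len(deps) == 1:
                progressed |= self._expand_input_bulk(tid, block, deps[0])
            else:
                progressed |= self._expand_input_joined(tid, block, deps)
        return progressed

    def _expand_input_incremental(self, tid, block, dep) -> bool:
        up = self.spec.task_by_ref(dep.target)
        progressed = False
        for rec in sorted(self.records.values(), key=lambda r: r.key):
            if rec.task_id != up.id or rec.state not in TERMINAL_SUCCESS:
                continue
            idx = rec.subtask_index
            if (tid, idx) in self.records:
                continue
            inst = _blocks.expand_input([rec], block.name)[0]
            inst = replace(inst, origin=(block.name, idx, inst.origin[2]))
            self.records[(tid, idx)] = SubtaskRecord(tid, idx, instance=inst)
            progressed = True
        if self._task_settled(up.id):
            self._expanded[tid] = True
        return progressed

    def _expand_input_bulk(self, tid, block, dep) -> bool:
        up = self.spec.task_by_ref(dep.target)
        if not self._task_settled(up.id):
            return False
        sources = [r for r in self.records.values()
                   if r.task_id == up.id and r.state in TERMINAL_SUCCESS]
        for inst in _blocks.expand_input(sources, block.name):
            rec = SubtaskRecord(tid, inst.ordinal, instance=inst)
            self.records[rec.key] = rec
        self._expanded[tid] = True
        return True

    def _expand_input_joined(self, tid, block, deps) -> bool:
        """compare_by_index join: one instance per index finished in ALL deps."""
        up_ids = [self.spec.task_by_ref(d.target).id for d in deps]
        progressed = False
        indices = None
        for uid in up_ids:
            done = {r.subtask_index for r in self.records.values()
                    if r.task_id == uid and r.state in TERMINAL_SUCCESS}
            indices = done if indices is None else indices & done
        for idx in sorted(indices or ()):
            if (tid, idx) in self.records:
                continue
            merged: dict[str, str] = {}
            for uid in up_ids:
                rv = self.records[(uid, idx)].return_values
                if not rv:
                    raise SchedulerError(
                        f"task {tid}: input dependency {uid}-{idx} returned no values")
                for k, v in rv.items():
                    if k in merged and merged[k] != v:
                        raise SchedulerError(
                            f"task {tid}: conflicting return value {k!r} at index {idx}")
                    merged[k] = v
            inst = _blocks.make_instance(merged, block.name, idx, source=f"join-{idx}")
            self.records[(tid, idx)] = SubtaskRecord(tid, idx, instance=inst)
            progressed = True
        if all(self._task_settled(uid) for uid in up_ids):
            self._expanded[tid] = True
        return progressed

    # -- rendering -----------------------------------------------------------

    def _render_argv(self, record: SubtaskRecord) -> tuple[str, ...]:
        task = self.spec.task_by_ref(record.task_id)
        module = self.registry.find(task.module_ref)
        params = record.param_overrides if record.param_overrides is not None else task.parameters
        assignments: dict[str, list[str]] = {}
        for name, template in params:
            value = (_blocks.substitute_placeholders(template, record.instance)
                     if record.instance is not None else template)
            assignments.setdefault(name, []).append(value)
        return tuple(render_command(module, assignments))

    def _substitute(self, template: str, record: SubtaskRecord) -> str:
        if record.instance is None:
            return template
        return _blocks.substitute_placeholders(template, record.instance)

    def _invocation(self, record: SubtaskRecord, argv) -> CommandInvocation:
        task = self.spec.task_by_ref(record.task_id)
        rid = f"t{record.task_id}-{record.subtask_index}.a{record.attempt}"
        stdout = (self._path(self._substitute(task.stdout_path, record))
                  if task.stdout_path else str(self.scratch / f"{rid}.out"))
        stderr = (self._path(self._substitute(task.stderr_path, record))
                  if task.stderr_path else str(self.scratch / f"{rid}.err"))
        return_file = str(self.scratch / f"{rid}.ret")
        Path(return_file).unlink(missing_ok=True)
        record.stdout_path, record.stderr_path, record.return_file = stdout, stderr, return_file
        return CommandInvocation(
            argv=tuple(argv),
            env=task.env,
            workdir=self.spec.base_dir,
            stdout_path=stdout,
            stderr_path=stderr,
            return_file=return_file,
        )

    def _path(self, p: str) -> str:
        pa = Path(p)
        return str(pa if pa.is_absolute() else Path(self.spec.base_dir) / pa)

    # -- scheduling ----------------------------------------------------------

    def _executor_for(self, task) -> object:
        name = task.executor_ref or self.spec.default_executor.name
        if name not in self.executors:
            raise SchedulerError(f"task {task.id}: no executor instance named {name!r}")
        return self.executors[name]

    def _running_count(self, task_id: int) -> int:
        return sum(1 for r in self.records.values()
                   if r.task_id == task_id and r.state is S.RUNNING)

    def _separate_edges(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        edges = []
        for t in self.spec.tasks:
            for dep in t.dependencies:
                if not dep.separate:
                    continue
                up = self.spec.task_by_ref(dep.target)
                for rec in self.records.values():
                    if rec.task_id == t.id:
                        m = 0 if (up.id, 0) in self.records else rec.subtask_index
                        if (up.id, m) in self.records:
                            edges.append(((up.id, m), rec.key))
        return edges

    def _host_constraint(self, record: SubtaskRecord, executor) -> str | None:
        if not getattr(executor, "slave_mode", False):
            return None
        assigned = {r.key: r.host for r in self.records.values() if r.host is not None}
        return apply_affinity(self._separate_edges(), assigned, record.key)

    def resolve_ready(self) -> list[SubtaskRecord]:
        """Launchable subtasks in ascending (task_id, subtask_index) order.

        A subtask is launchable when every task-level dependency is fully
        successful, every separate dependency is index-match successful, no
        upstream checkpoint is unreleased, and the per-task cap leaves room.
        Per-executor slots are enforced at launch by the executor itself.
        """
        out = []
        for key in sorted(self.records):
            rec = self.records[key]
            if rec.state not in (S.PENDING, S.READY, S.HELD_RESOURCE, S.HELD_CHECKPOINT):
                continue
            if self._dep_status(rec) != "ok" or self._checkpoint_holds(rec):
                continue
            task = self.spec.task_by_ref(rec.task_id)
            if (task.max_running is not None and not rec.hold_released
                    and self._running_count(rec.task_id) >= task.max_running):
                continue
            out.append(rec)
        return out

    def _pump(self) -> bool:
        """One scheduling sweep; returns True if any state changed."""
        progressed = self._expand_inputs()
        for key in sorted(self.records):
            rec = self.records[key]
            if rec.state is S.PENDING:
                if self._dep_status(rec) == "ok":
                    apply_transition(rec, "ready")
                    self.trace.add(self.now(), *key, "ready")
                    progressed = True
            if rec.state in (S.READY, S.HELD_RESOURCE, S.HELD_CHECKPOINT):
                progressed |= self._try_launch(rec)
        return progressed

    def _try_launch(self, rec: SubtaskRecord) -> bool:
        task = self.spec.task_by_ref(rec.task_id)
        if self._checkpoint_holds(rec):
            if rec.state is S.READY:
                apply_transition(rec, "hold_checkpoint")
                self.trace.add(self.now(), *rec.key, "held_checkpoint")
                return True
            return False
        if rec.state is S.HELD_CHECKPOINT:
            apply_transition(rec, "release")
            self.trace.add(self.now(), *rec.key, "released")
        if (task.max_running is not None and not rec.hold_released
                and self._running_count(rec.task_id) >= task.max_running):
            if rec.state is S.READY:
                apply_transition(rec, "hold_resource")
                self.trace.add(self.now(), *rec.key, "held_resource")
                return True
            return False

        argv = self._render_argv(rec)
        if self.journal is not None:
            replay_returns = self.journal.match_succeeded(rec.task_id, rec.subtask_index, argv)
            if replay_returns is not None:
                if rec.state is S.HELD_RESOURCE:
                    apply_transition(rec, "release")
                    self.trace.add(self.now(), *rec.key, "released")
                rec.resolved_argv = argv
                apply_transition(rec, "replay", return_values=replay_returns)
                self.trace.add(self.now(), *rec.key, "replayed")
                return True

        executor = self._executor_for(task)
        try:
            constraint = self._host_constraint(rec, executor)
        except ExecutorError as exc:
            return self._fail_before_launch(rec, argv, str(exc))
        try:
            run_task_actions(task.task_actions, "before",
                             lambda s: self._substitute(s, rec), self.spec.base_dir)
        except TaskActionError as exc:
            return self._fail_before_launch(rec, argv, str(exc))
        inv = self._invocation(rec, argv)
        host = executor.try_launch(rec.key, inv, host_constraint=constraint)
        if host is None:
            if rec.state is S.READY:
                apply_transition(rec, "hold_resource")
                self.trace.add(self.now(), *rec.key, "held_resource")
                return True
            return False
        if rec.state is S.HELD_RESOURCE:
            apply_transition(rec, "release")
            self.trace.add(self.now(), *rec.key, "released")
        rec.resolved_argv = argv
        rec.host = host
        apply_transition(rec, "launch")
        self.trace.add(self.now(), *rec.key, "running", host=host)
        return True

    def _fail_before_launch(self, rec, argv, message) -> bool:
        if rec.state is S.HELD_RESOURCE:
            apply_transition(rec, "release")
            self.trace.add(self.now(), *rec.key, "released")
        rec.resolved_argv = tuple(argv)
        apply_transition(rec, "launch")
        self.trace.add(self.now(), *rec.key, "running", host=None)
        rec.exit_code = -1
        rec.messages.append(message)
        apply_transition(rec, "fail")
        self.trace.add(self.now(), *rec.key, "failed_awaiting_user")
        return True

    # -- judgment --------------------------------------------------------------

    def _judge(self, completion) -> None:
        rec = self.records[completion.key]
        task = self.spec.task_by_ref(rec.task_id)
        rec.exit_code = completion.exit_code
        if completion.message:
            rec.messages.append(completion.message)
        artifacts = Artifacts(rec.stdout_path, rec.stderr_path, rec.return_file)
        verdict = judge_result(rec, task.checkers, artifacts)
        t = completion.end_time if self.clock is not None else self.now()
        if verdict.final == "SUCCESS":
            returns = dict(completion.return_values)
            if self.dry_run and not returns:
                # synthesize declared returns so input blocks expand in a dry run
                module = self.registry.find(task.module_ref)
                stub = {"integer": "1", "double": "1.0", "boolean": "true"}
                returns = {r.name: stub.get(r.value_type, f"dry-{rec.label()}-{r.name}.tmp")
                           for r in module.returns}
            self._typecheck_returns(task, returns)
            self._after_actions(task, rec, "after_success")
            apply_transition(rec, "succeed", return_values=returns)
            self.trace.add(t, *rec.key, "succeeded", host=completion.host)
            if self.journal is not None:
                self.journal.record(rec)
        else:
            rec.messages.extend(m for m in verdict.messages if m not in rec.messages)
            self._after_actions(task, rec, "after_failure")
            apply_transition(rec, "fail")
            self.trace.add(t, *rec.key, "failed_awaiting_user", host=completion.host)
            logger.warning("subtask %s failed on %s: argv=%s exit=%s messages=%s",
                           rec.label(), completion.host, list(rec.resolved_argv or ()),
                           rec.exit_code, rec.messages)

    def _typecheck_returns(self, task, returns: dict) -> None:
        module = self.registry.find(task.module_ref)
        for r in module.returns:
            if r.name in returns:
                r.parse_value(returns[r.name])

    def _after_actions(self, task, rec, phase: str) -> None:
        try:
            run_task_actions(task.task_actions, phase,
                             lambda s: self._substitute(s, rec), self.spec.base_dir)
        except TaskActionError as exc:
            logger.warning("subtask %s: %s action failed: %s", rec.label(), phase, exc)

    # -- user actions ------------------------------------------------------------

    def post_action(self, task_id: int, subtask_index: int, action: str, **kwargs) -> None:
        """Queue a user action for the run loop (thread-safe)."""
        with self._lock:
            self._actions.append((task_id, subtask_index, action, kwargs))

    def _drain_actions(self) -> bool:
        with self._lock:
            pending, self._actions = self._actions, []
        acted = False
        for tid, idx, action, kwargs in pending:
            self.act(tid, idx, action, **kwargs)
            acted = True
        return acted

    def act(self, task_id: int, subtask_index: int, action: str,
            params: Mapping[str, str] | None = None,
            returns: Mapping[str, str] | None = None) -> bool:
        """Apply one recovery/interaction action.

        Repeat delivery of an action whose target state was already reached is
        a no-op (returns False); an action illegal for the current state
        raises :class:`TransitionError`.
        """
        with self._lock:
            if action == "release_checkpoint":
                self.release_checkpoint(task_id)
                return True
            key = (task_id, subtask_index)
            if key not in self.records:
                raise SchedulerError(f"unknown subtask {task_id}-{subtask_index}")
            rec = self.records[key]
            if action == "release_resource_hold":
                rec.hold_released = True
                return True
            idempotent_target = {
                "ignore": S.IGNORED,
                "resolve": S.RESOLVED_MANUAL,
                "restart": S.READY,
                "modify_restart": S.READY,
            }.get(action)
            if idempotent_target is not None and rec.state is idempotent_target:
                return False
            if action == "restart":
                apply_transition(rec, "user_restart")
            elif action == "modify_restart":
                overrides = tuple((params or {}).items()) if params is not None else None
                apply_transition(rec, "user_modify_restart", param_overrides=overrides)
            elif action == "ignore":
                apply_transition(rec, "user_ignore")
            elif action == "resolve":
                task = self.spec.task_by_ref(task_id)
                module = self.registry.find(task.module_ref)
                resolve_manually(rec, dict(returns or {}), module)
                if self.journal is not None:
                    self.journal.record(rec)
            else:
                raise SchedulerError(f"unknown action {action!r}")
            self.trace.add(self.now(), task_id, subtask_index,
                           rec.state.name.lower())
            return True

    def release_checkpoint(self, task_ref: str | int) -> None:
        task = self.spec.task_by_ref(task_ref)
        if not task.checkpoint:
            raise SchedulerError(f"task {task.id} has no checkpoint")
        self.released_checkpoints.add(task.id)
        self.trace.add(self.now(), task.id, 0, "checkpoint_released")

    # -- main loop -----------------------------------------------------------------

    def _any_running(self) -> bool:
        return any(r.state is S.RUNNING for r in self.records.values())

    def _wait_any(self) -> list:
        while True:
            completions = []
            for ex in self.executors.values():
                completions.extend(ex.poll())
            if completions:
                return sorted(completions, key=lambda c: (c.end_time, c.key))
            virt = [ex for ex in self.executors.values()
                    if isinstance(ex, VirtualExecutor) and ex.busy_count()]
            if virt:
                target = min(ex.next_event_time() for ex in virt)
                self.clock.time = max(self.clock.time, target)
                continue
            if not self._any_running():
                return []
            self._drain_actions()
            _time.sleep(0.01)

    def run(self, action_handler: Callable[["Engine"], bool] | None = None,
            wait_for_user: bool = False):
        """Drive the run to quiescence; returns (records, trace).

        When subtasks end blocked on user action, ``action_handler`` (if any)
        is invoked and the loop continues while it reports progress; with
        ``wait_for_user`` the engine instead polls the action queue (used when
        a status/action server is attached).  Subtasks held at an unreleased
        checkpoint with no interaction channel raise :class:`DeadlockError`.
        """
        while True:
            self._drain_actions()
            progressed = self._pump()
            if self._any_running():
                for completion in self._wait_any():
                    self._judge(completion)
                continue
            if progressed:
                continue
            failed = [r for r in self.records.values()
                      if r.state is S.FAILED_AWAITING_USER]
            held_cp = [r for r in self.records.values() if r.state is S.HELD_CHECKPOINT]
            if failed or held_cp:
                if action_handler is not None and action_handler(self):
                    continue
                if wait_for_user:
                    _time.sleep(0.02)
                    continue
                if held_cp:
                    raise DeadlockError(
                        "subtasks held at an unreleased checkpoint with no interaction "
                        f"channel: {sorted(r.label() for r in held_cp)}",
                        blocked={r.key for r in held_cp},
                    )
                break
            stuck = [r for r in self.records.values()
                     if r.state not in TERMINAL and r.state is not S.FAILED_AWAITING_USER]
            if stuck:
                ignored = {r.task_id for r in self.records.values() if r.state is S.IGNORED}
                blocked = [
                    r for r in stuck
                    if r.state is S.PENDING
                    and (self._dep_status(r) == "blocked"
                         or nx.ancestors(self.graph, r.task_id) & ignored)
                ]
                if len(blocked) == len(stuck):
                    break  # blocked by an ignored upstream failure; contained
                raise DeadlockError(
                    f"no runnable subtask, nothing running, no user action pending: "
                    f"{sorted(r.label() for r in stuck)}",
                    blocked={r.key for r in stuck},
                )
            break
        return self.records, self.trace

    # -- summary ---------------------------------------------------------------

    def all_successful(self) -> bool:
        """True iff every active task fully expanded and all subtasks succeeded."""
        if not all(self._expanded.get(t.id, False) for t in self.spec.tasks
                   if t.id in self.active):
            return False
        return all(r.state in TERMINAL_SUCCESS | {S.EXCLUDED}
                   for r in self.records.values())

    def counters(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records.values():
            out[r.state.name.lower()] = out.get(r.state.name.lower(), 0) + 1
        return out


def run_workflow(
    spec: WorkflowSpec,
    registry: ModuleRegistry,
    executors: Mapping[str, object] | None = None,
    filter: ScopeFilter | None = None,
    resume_journal: str | Path | None = None,
    action_handler: Callable | None = None,
    **engine_kwargs,
):
    """Convenience wrapper: build an engine and run it to quiescence."""
    engine = Engine(spec, registry, executors=executors, scope=filter,
                    journal_path=resume_journal, **engine_kwargs)
    return engine.run(action_handler=action_handler)
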