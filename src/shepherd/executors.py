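"""Command executors.

Two executors are fully functional:

* :class:`LocalExecutor` spawns real child processes on the machine running
  the engine, with a hard cap on concurrent children.
* :class:`VirtualExecutor` is a deterministic discrete-event simulator used
  for trace-level tests and ``--dry-run``: each launch occupies one slot on a
  simulated host for a scripted duration and then reports a scripted exit
  code and return values.  Identical configuration and launch order always
  yield an identical trace.

Remote (SSH) and cluster back-ends are declared in the workflow dialect and
registered here as stubs so such workflows parse; launching on them raises.
New executor types can be registered with :func:`register_executor_type`.

Return values travel from a child process to the engine through a per-subtask
TSV file (``key<TAB>value`` rows) whose path is exported in the environment
variable ``WATCHDOG_RETURN_FILE``.
"""

from __future__ import annotations

import heapq
import os
import shutil
import subprocess
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .exceptions import ExecutorError, TaskActionError

RETURN_FILE_ENV = "WATCHDOG_RETURN_FILE"

SubtaskKey = tuple[int, int]  # (task_id, subtask_index)


@dataclass(frozen=True)
class CommandInvocation:
    argv: tuple[str, ...]
    env: tuple[tuple[str, str], ...] = ()
    workdir: str = "."
    stdout_path: str | None = None
    stderr_path: str | None = None
    return_file: str | None = None

    def __post_init__(self):
        if not self.argv:
            raise ExecutorError("invocation argv must be non-empty")

    def full_env(self) -> dict[str, str]:
        env = dict(os.environ)
        env.update(dict(self.env))
        if self.return_file:
            env[RETURN_FILE_ENV] = self.return_file
        return env


@dataclass(frozen=True)
class Completion:
    key: SubtaskKey
    exit_code: int
    return_values: dict
    host: str
    end_time: float
    message: str | None = None


def parse_return_file(path: str | None) -> dict[str, str]:
    """Parse a ``key<TAB>value`` TSV return file; absent file means no returns."""
    if not path or not Path(path).exists():
        return {}
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise ExecutorError(f"{path}:{lineno}: return file line has no tab separator")
        key, value = line.split("\t", 1)
        out[key] = value
    return out


class Executor:
    """Common executor surface used by the scheduling engine."""

    name = "executor"
    max_slots = 1

    def try_launch(self, key: SubtaskKey, inv: CommandInvocation,
                   host_constraint: str | None = None) -> str | None:
        """Start the command if a slot is free; return the host, else None."""
        raise NotImplementedError

    def poll(self) -> list[Completion]:
        """Return completions that have become available (non-blocking)."""
        raise NotImplementedError

    def busy_count(self) -> int:
        raise NotImplementedError

    def next_event_time(self) -> float | None:
        """Virtual executors: simulated time of the next completion."""
        return None

    def advance(self) -> None:
        """Virtual executors: jump the shared clock to the next completion."""


class LocalExecutor(Executor):
    """Runs commands as child processes; never exceeds ``max_slots`` children."""

    def __init__(self, max_slots: int = 1, name: str = "local"):
        if max_slots < 1:
            raise ExecutorError("max_slots must be positive")
        self.name = name
        self.max_slots = max_slots
        self._running: dict[SubtaskKey, tuple[subprocess.Popen, CommandInvocation, list]] = {}
        self._immediate: list[Completion] = []
        self._t0 = time.monotonic()

    def _now(self) -> float:
        return round(time.monotonic() - self._t0, 6)

    def try_launch(self, key, inv, host_constraint=None):
        if len(self._running) >= self.max_slots:
            return None
        handles = []
        try:
            stdout = self._open(inv.stdout_path, handles)
            stderr = self._open(inv.stderr_path, handles)
            proc = subprocess.Popen(
                list(inv.argv),
                cwd=inv.workdir,
                env=inv.full_env(),
                stdout=stdout,
                stderr=stderr,
            )
        except OSError as exc:
            for h in handles:
                h.close()
            # spawn failure: surfaced as exit code -1
            self._immediate.append(
                Completion(key, -1, {}, self.name, self._now(), message=str(exc))
            )
            return self.name
        self._running[key] = (proc, inv, handles)
        return self.name

    @staticmethod
    def _open(path: str | None, handles: list):
        if path is None:
            return subprocess.DEVNULL
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fh = open(path, "wb")
        handles.append(fh)
        return fh

    def poll(self) -> list[Completion]:
        done, out = [], list(self._immediate)
        self._immediate.clear()
        for key, (proc, inv, handles) in self._running.items():
            code = proc.poll()
            if code is None:
                continue
            for h in handles:
                h.close()
            message = None
            returns: dict = {}
            try:
                returns = parse_return_file(inv.return_file)
            except ExecutorError as exc:
                message, code = str(exc), (code if code != 0 else -1)
            out.append(Completion(key, code, returns, self.name, self._now(), message))
            done.append(key)
        for key in done:
            del self._running[key]
        return out

    def busy_count(self) -> int:
        return len(self._running)


def execute_local(inv: CommandInvocation, slots: threading.Semaphore) -> tuple[int, dict]:
    """Run one invocation synchronously under a shared slot semaphore."""
    with slots:
        handles: list = []
        try:
            stdout = LocalExecutor._open(inv.stdout_path, handles)
            stderr = LocalExecutor._open(inv.stderr_path, handles)
            try:
                proc = subprocess.run(
                    list(inv.argv), cwd=inv.workdir, env=inv.full_env(),
                    stdout=stdout, stderr=stderr,
                )
                code = proc.returncode
            except OSError:
                return -1, {}
        finally:
            for h in handles:
                h.close()
    return code, parse_return_file(inv.return_file)


# --------------------------------------------------------------------------- virtual

class VirtualClock:
    """Simulated time shared by all virtual executors of one engine run."""

    def __init__(self):
        self.time = 0.0


@dataclass
class VirtualExecutorConfig:
    """Scripted behavior of a virtual executor.

    Durations default to 1.0 simulated time units, exit codes to 0.  Keys are
    (task_id, subtask_index).
    """

    hosts: int = 1
    slots_per_host: int = 1
    duration_of: dict = field(default_factory=dict)
    exit_code_of: dict = field(default_factory=dict)
    returns_of: dict = field(default_factory=dict)
    default_duration: float = 1.0
    slave_mode: bool = False

    def __post_init__(self):
        if self.hosts < 1 or self.slots_per_host < 1:
            raise ExecutorError("hosts and slots_per_host must be positive")
        if self.default_duration <= 0 or any(d <= 0 for d in self.duration_of.values()):
            raise ExecutorError("durations must be > 0")


class VirtualExecutor(Executor):
    """Deterministic discrete-event executor.

    Host assignment is the lowest-index host with a free slot; under slave
    mode the engine passes a host constraint instead (dependent subtasks share
    a host) and the launch waits until that host has a free slot.
    """

    def __init__(self, config: VirtualExecutorConfig, clock: VirtualClock | None = None,
                 name: str = "virtual"):
        self.name = name
        self.config = config
        self.clock = clock or VirtualClock()
        self.max_slots = config.hosts * config.slots_per_host
        self._free = {f"host{i + 1}": config.slots_per_host for i in range(config.hosts)}
        self._events: list[tuple[float, int, SubtaskKey, str]] = []
        self._seq = 0

    @property
    def slave_mode(self) -> bool:
        return self.config.slave_mode

    def try_launch(self, key, inv, host_constraint=None):
        if host_constraint is not None:
            if host_constraint not in self._free:
                raise ExecutorError(f"unknown host {host_constraint!r} on executor {self.name!r}")
            host = host_constraint if self._free[host_constraint] > 0 else None
        else:
            host = next((h for h in self._free if self._free[h] > 0), None)
        if host is None:
            return None
        self._free[host] -= 1
        duration = float(self.config.duration_of.get(key, self.config.default_duration))
        heapq.heappush(self._events, (self.clock.time + duration, self._seq, key, host))
        self._seq += 1
        return host

    def next_event_time(self) -> float | None:
        return self._events[0][0] if self._events else None

    def advance(self) -> None:
        if self._events:
            self.clock.time = max(self.clock.time, self._events[0][0])

    def poll(self) -> list[Completion]:
        out = []
        while self._events and self._events[0][0] <= self.clock.time + 1e-12:
            end, _, key, host = heapq.heappop(self._events)
            self._free[host] += 1
            out.append(
                Completion(
                    key=key,
                    exit_code=int(self.config.exit_code_of.get(key, 0)),
                    return_values=dict(self.config.returns_of.get(key, {})),
                    host=host,
                    end_time=end,
                )
            )
        return out

    def busy_count(self) -> int:
        return len(self._events)


def apply_affinity(
    edges: Sequence[tuple[SubtaskKey, SubtaskKey]],
    assigned: Mapping[SubtaskKey, str],
    key: SubtaskKey,
) -> str | None:
    """Host constraint for `key` under slave mode.

    Any subtask connected to an already-placed subtask by a subtask-level
    dependency edge must receive the same host.  Conflicting constraints from
    two different hosts are a scheduling error.
    """
    hosts = set()
    for u, v in edges:
        other = u if v == key else (v if u == key else None)
        if other is not None and other in assigned:
            hosts.add(assigned[other])
    if len(hosts) > 1:
        raise ExecutorError(
            f"subtask {key} is affinity-linked to multiple hosts: {sorted(hosts)}"
        )
    return hosts.pop() if hosts else None


# --------------------------------------------------------------------------- task actions

def run_task_actions(actions, phase: str, substitute: Callable[[str], str],
                     base_dir: str = ".") -> None:
    """Execute the task actions of one phase, in declaration order.

    ``create`` makes a directory when the path ends with "/", else an empty
    file (parents created); ``delete`` removes a file or directory tree;
    ``copy`` copies a file or tree.  Paths are placeholder-substituted and
    resolved against the workflow directory.  Failures raise
    :class:`TaskActionError`; the engine fails the subtask for ``before``
    actions and logs for ``after_*`` ones.
    """
    for a in actions:
        if a.phase != phase:
            continue
        src = _resolve(substitute(a.src), base_dir)
        try:
            if a.action == "create":
                if a.src.endswith("/"):
                    src.mkdir(parents=True, exist_ok=True)
                else:
                    src.parent.mkdir(parents=True, exist_ok=True)
                    src.touch()
            elif a.action == "delete":
                if src.is_dir():
                    shutil.rmtree(src)
                elif src.exists():
                    src.unlink()
                else:
                    raise FileNotFoundError(f"delete target does not exist: {src}")
            elif a.action == "copy":
                dst = _resolve(substitute(a.dst), base_dir)
                dst.parent.mkdir(parents=True, exist_ok=True)
                if src.is_dir():
                    shutil.copytree(src, dst, dirs_exist_ok=True)
                else:
                    shutil.copy2(src, dst)
        except (OSError, FileNotFoundError) as exc:
            raise TaskActionError(f"task action {a.action} {a.src!r} failed: {exc}") from exc


def _resolve(path: str, base_dir: str) -> Path:
    p = Path(path)
    return p if p.is_absolute() else Path(base_dir) / p


# --------------------------------------------------------------------------- registry

#: executor type name -> factory(decl attributes: dict, max_slots: int,
#: clock: VirtualClock | None) -> Executor
_EXECUTOR_TYPES: dict[str, Callable] = {}


def register_executor_type(type_name: str, factory: Callable) -> None:
    _EXECUTOR_TYPES[type_name] = factory


def executor_types() -> dict:
    return dict(_EXECUTOR_TYPES)


class StubExecutor(Executor):
    """Placeholder for remote/cluster back-ends: declared, never launched."""

    def __init__(self, type_name: str, name: str, max_slots: int = 1):
        self.type_name = type_name
        self.name = name
        self.max_slots = max_slots

    def try_launch(self, key, inv, host_constraint=None):
        raise ExecutorError(
            f"executor {self.name!r} ({self.type_name}) is not configured in this build"
        )

    def poll(self):
        return []

    def busy_count(self):
        return 0


def _local_factory(attrs, max_slots, clock=None, name="local"):
    return LocalExecutor(max_slots=max_slots, name=name)


def _virtual_factory(attrs, max_slots, clock=None, name="virtual"):
    hosts = int(attrs.get("hosts", "1"))
    slots = int(attrs.get("slotsPerHost", str(max(1, max_slots // max(hosts, 1)))))
    slave = attrs.get("slave", "false").lower() in ("true", "1", "yes")
    cfg = VirtualExecutorConfig(hosts=hosts, slots_per_host=slots, slave_mode=slave)
    return VirtualExecutor(cfg, clock=clock, name=name)


register_executor_type("local", _local_factory)
register_executor_type("virtual", _virtual_factory)
for _stub in ("ssh", "drmaa", "slurm"):
    register_executor_type(
        _stub,
        lambda attrs, max_slots, clock=None, name="stub", _t=_stub: StubExecutor(
            _t, name=name, max_slots=max_slots
        ),
    )


def build_executor(decl, clock: VirtualClock | None = None) -> Executor:
    """Instantiate an executor from a workflow declaration."""
    if decl.exec_type not in _EXECUTOR_TYPES:
        raise ExecutorError(f"unknown executor type {decl.exec_type!r}")
    return _EXECUTOR_TYPES[decl.exec_type](
        decl.attr_map, decl.max_slots, clock=clock, name=decl.name
    )
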