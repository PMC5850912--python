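"""Workflow XML dialect: parsing, constant resolution, static validation.

A workflow file has root ``<watchdog>`` with two children:

* ``<settings>`` — constants, executor declarations, process blocks and
  module search folders,
* ``<tasks>`` — one element per task, named after the module it runs
  (e.g. ``<sleepTask id="1" name="sleep">``), carrying parameters,
  dependencies, stream redirects, environment variables, task actions and
  checkers.

Constants are referenced as ``${NAME}`` inside parameter/path/env templates
and resolved by :func:`resolve_constants` before scheduling; instance
placeholders (``{}``, ``[k]``, ``{$var}``) are left for per-subtask
substitution.
"""

from __future__ import annotations

import logging
import re
import shlex
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
from lxml import etree

from . import blocks
from .checks import CheckerDecl
from .exceptions import WorkflowError
from .modules import ModuleRegistry

logger = logging.getLogger(__name__)

CONST_RE = re.compile(r"\$\{([A-Za-z_][A-Za-z0-9_]*)\}")
EXECUTOR_TYPES = ("local", "virtual")  # anything else resolves via the executor plugin registry


@dataclass(frozen=True)
class ExecutorDecl:
    name: str
    exec_type: str = "local"
    max_slots: int = 1
    default: bool = False
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if not self.name:
            raise WorkflowError("executor name must be non-empty")
        if self.max_slots < 1:
            raise WorkflowError(f"executor {self.name!r}: maxSlots must be positive")

    @property
    def attr_map(self) -> dict[str, str]:
        return dict(self.attributes)


@dataclass(frozen=True)
class DependencyDecl:
    target: str  # task id (as text) or task name
    separate: bool = False


@dataclass(frozen=True)
class TaskAction:
    phase: str  # before | after_success | after_failure
    action: str  # create | delete | copy
    src: str
    dst: str | None = None

    def __post_init__(self):
        if self.phase not in ("before", "after_success", "after_failure"):
            raise WorkflowError(f"unknown task-action phase {self.phase!r}")
        if self.action not in ("create", "delete", "copy"):
            raise WorkflowError(f"unknown task-action type {self.action!r}")
        if self.action == "copy" and not self.dst:
            raise WorkflowError("copy task action requires a dst path")


@dataclass(frozen=True)
class TaskSpec:
    id: int
    name: str
    module_ref: str
    parameters: tuple[tuple[str, str], ...] = ()  # ordered (name, template)
    dependencies: tuple[DependencyDecl, ...] = ()
    process_block_ref: str | None = None
    executor_ref: str | None = None
    max_running: int | None = None
    checkpoint: bool = False
    stdout_path: str | None = None
    stderr_path: str | None = None
    env: tuple[tuple[str, str], ...] = ()
    task_actions: tuple[TaskAction, ...] = ()
    checkers: tuple[CheckerDecl, ...] = ()

    def __post_init__(self):
        if self.id < 1:
            raise WorkflowError(f"task id must be a positive integer, got {self.id}")
        if not self.name:
            raise WorkflowError(f"task {self.id}: name must be non-empty")
        if self.max_running is not None and self.max_running < 1:
            raise WorkflowError(f"task {self.id}: maxRunning must be positive")

    @property
    def param_map(self) -> dict[str, str]:
        return dict(self.parameters)


@dataclass(frozen=True)
class WorkflowSpec:
    constants: tuple[tuple[str, str], ...] = ()
    executors: tuple[ExecutorDecl, ...] = ()
    blocks: tuple = ()
    module_folders: tuple[str, ...] = ()
    tasks: tuple[TaskSpec, ...] = ()
    base_dir: str = "."

    @property
    def const_map(self) -> dict[str, str]:
        return dict(self.constants)

    def task_by_ref(self, ref: str | int) -> TaskSpec:
        """Resolve a task reference given as id (number) or name."""
        text = str(ref)
        for t in self.tasks:
            if text == str(t.id) or text == t.name:
                return t
        raise WorkflowError(f"no task with id or name {text!r}")

    def block_by_name(self, name: str):
        for b in self.blocks:
            if b.name == name:
                return b
        raise WorkflowError(f"no process block named {name!r}")

    def executor_by_name(self, name: str) -> ExecutorDecl:
        for e in self.executors:
            if e.name == name:
                return e
        raise WorkflowError(f"no executor named {name!r}")

    @property
    def default_executor(self) -> ExecutorDecl:
        for e in self.executors:
            if e.default:
                return e
        if self.executors:
            return self.executors[0]
        return ExecutorDecl(name="local", exec_type="local", max_slots=1, default=True)


@dataclass(frozen=True)
class Diagnostic:
    task_id: int | None
    message: str

    def __str__(self):
        where = f"task {self.task_id}" if self.task_id is not None else "workflow"
        return f"{where}: {self.message}"


# --------------------------------------------------------------------------- parsing

def parse_workflow(xml_path: str | Path, registry: ModuleRegistry | None = None) -> WorkflowSpec:
    """Parse a workflow file and enforce all parse-time invariants.

    Constants are *not* substituted here; run :func:`resolve_constants` on the
    result.  When a registry is given, task elements must name a known module.
    """
    path = Path(xml_path)
    if not path.exists():
        raise WorkflowError(f"workflow file not found: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise WorkflowError(f"{path}: XML syntax error: {exc}") from exc
    root = tree.getroot()
    if root.tag != "watchdog":
        raise WorkflowError(f"{path}: root element must be <watchdog>, got <{root.tag}>")

    base_dir = str(path.parent.resolve())
    constants: list[tuple[str, str]] = []
    executors: list[ExecutorDecl] = []
    block_decls: list = []
    module_folders: list[str] = []
    tasks: list[TaskSpec] = []

    settings = root.find("settings")
    if settings is not None:
        constants = _parse_constants(settings)
        executors = _parse_executors(settings)
        block_decls = _parse_blocks(settings)
        module_folders = [
            el.get("path")
            for el in settings.findall("moduleFolders/folder")
            if el.get("path")
        ]

    tasks_el = root.find("tasks")
    if tasks_el is not None:
        if tasks_el.get("mail"):
            logger.info("tasks: mail attribute %r parsed and ignored", tasks_el.get("mail"))
        for el in tasks_el:
            if el.tag is etree.Comment:
                continue
            tasks.append(_parse_task(el))

    spec = WorkflowSpec(
        constants=tuple(constants),
        executors=tuple(executors),
        blocks=tuple(block_decls),
        module_folders=tuple(module_folders),
        tasks=tuple(tasks),
        base_dir=base_dir,
    )
    _check_spec_invariants(spec, registry)
    return spec


def _parse_constants(settings) -> list[tuple[str, str]]:
    out = []
    seen = set()
    for el in settings.findall("constants/const"):
        name, value = el.get("name"), el.get("value")
        if name is None or value is None:
            raise WorkflowError("<const> requires 'name' and 'value' attributes")
        if not CONST_RE.fullmatch("${%s}" % name):
            raise WorkflowError(f"invalid constant name {name!r}")
        if name in seen:
            raise WorkflowError(f"duplicate constant {name!r}")
        seen.add(name)
        out.append((name, value))
    return out


_EXECUTOR_KNOWN_ATTRS = {"name", "type", "maxSlots", "default"}


def _parse_executors(settings) -> list[ExecutorDecl]:
    out = []
    names = set()
    defaults = 0
    for el in settings.findall("executors/executor"):
        name = el.get("name")
        if not name:
            raise WorkflowError("<executor> requires a 'name' attribute")
        if name in names:
            raise WorkflowError(f"duplicate executor {name!r}")
        names.add(name)
        is_default = el.get("default", "false").lower() in ("true", "1", "yes")
        defaults += is_default
        extra = tuple(
            (k, v) for k, v in sorted(el.attrib.items()) if k not in _EXECUTOR_KNOWN_ATTRS
        )
        out.append(
            ExecutorDecl(
                name=name,
                exec_type=el.get("type", "local"),
                max_slots=int(el.get("maxSlots", "1")),
                default=is_default,
                attributes=extra,
            )
        )
    if defaults > 1:
        raise WorkflowError("at most one executor may be marked default")
    return out


def _parse_blocks(settings) -> list:
    out = []
    names = set()
    container = settings.find("processBlock")
    if container is None:
        return out
    for el in container:
        if el.tag is etree.Comment:
            continue
        decl = blocks.parse_block_element(el.tag, dict(el.attrib))
        if decl.name in names:
            raise WorkflowError(f"duplicate process block {decl.name!r}")
        names.add(decl.name)
        out.append(decl)
    return out


def _parse_task(el) -> TaskSpec:
    module_ref = el.tag
    if el.get("id") is None or el.get("name") is None:
        raise WorkflowError(f"<{module_ref}> task requires 'id' and 'name' attributes")
    params: list[tuple[str, str]] = []
    deps: list[DependencyDecl] = []
    actions: list[TaskAction] = []
    checkers: list[CheckerDecl] = []
    env: list[tuple[str, str]] = []
    stdout_path = stderr_path = None
    for child in el:
        if child.tag is etree.Comment:
            continue
        if child.tag == "parameter":
            for p in child:
                if p.tag is etree.Comment:
                    continue
                params.append((p.tag, p.text or ""))
        elif child.tag == "dependencies":
            for d in child.findall("depends"):
                target = (d.text or "").strip()
                if not target:
                    raise WorkflowError(f"task {el.get('id')}: empty dependency target")
                sep = d.get("separate", "false").lower() in ("true", "1", "yes")
                deps.append(DependencyDecl(target=target, separate=sep))
        elif child.tag == "streams":
            so = child.find("stdout")
            se = child.find("stderr")
            stdout_path = so.get("path") if so is not None else None
            stderr_path = se.get("path") if se is not None else None
        elif child.tag == "environment":
            for v in child.findall("var"):
                env.append((v.get("name"), v.get("value", "")))
        elif child.tag == "actions":
            for a in child.findall("action"):
                actions.append(
                    TaskAction(
                        phase=a.get("phase", "before"),
                        action=a.get("type", "create"),
                        src=a.get("src", ""),
                        dst=a.get("dst"),
                    )
                )
        elif child.tag == "checkers":
            for i, c in enumerate(child.findall("checker")):
                checkers.append(_parse_checker(c, i))
        else:
            raise WorkflowError(f"task {el.get('id')}: unknown element <{child.tag}>")
    notify = el.get("notify")
    if notify:
        logger.info("task %s: notify attribute %r parsed and ignored", el.get("id"), notify)
    return TaskSpec(
        id=int(el.get("id")),
        name=el.get("name"),
        module_ref=module_ref,
        parameters=tuple(params),
        dependencies=tuple(deps),
        process_block_ref=el.get("processBlock"),
        executor_ref=el.get("executor"),
        max_running=int(el.get("maxRunning")) if el.get("maxRunning") else None,
        checkpoint=el.get("checkpoint", "false").lower() in ("true", "1", "yes"),
        stdout_path=stdout_path,
        stderr_path=stderr_path,
        env=tuple(env),
        task_actions=tuple(actions),
        checkers=tuple(checkers),
    )


def _parse_checker(el, order: int) -> CheckerDecl:
    name = el.get("name")
    if not name:
        raise WorkflowError("<checker> requires a 'name' attribute")
    args = []
    raw = el.get("args", "")
    if raw:
        for piece in raw.split(","):
            if ":" not in piece:
                raise WorkflowError(f"checker {name!r}: argument {piece!r} must be type:value")
            typ, value = piece.split(":", 1)
            args.append((value, typ.strip()))
    return CheckerDecl(
        checker_name=name, kind=el.get("kind", "error"), ctor_args=tuple(args), order=order
    )


def _check_spec_invariants(spec: WorkflowSpec, registry: ModuleRegistry | None) -> None:
    ids, names = set(), set()
    for t in spec.tasks:
        if t.id in ids:
            raise WorkflowError(f"duplicate task id {t.id}")
        if t.name in names:
            raise WorkflowError(f"duplicate task name {t.name!r}")
        ids.add(t.id)
        names.add(t.name)
    block_names = {b.name for b in spec.blocks}
    executor_names = {e.name for e in spec.executors}
    g = nx.DiGraph()
    g.add_nodes_from(t.id for t in spec.tasks)
    for t in spec.tasks:
        if t.process_block_ref is not None and t.process_block_ref not in block_names:
            raise WorkflowError(f"task {t.id}: unresolved process block {t.process_block_ref!r}")
        if t.executor_ref is not None and t.executor_ref not in executor_names:
            raise WorkflowError(f"task {t.id}: unresolved executor {t.executor_ref!r}")
        for d in t.dependencies:
            target = spec.task_by_ref(d.target)  # raises on unresolved
            g.add_edge(target.id, t.id)
        if registry is not None and t.module_ref not in registry:
            raise WorkflowError(f"task {t.id}: unknown module element <{t.module_ref}>")
    try:
        cycle = nx.find_cycle(g)
        raise WorkflowError(f"dependency cycle among tasks: {[e[0] for e in cycle]}")
    except nx.NetworkXNoCycle:
        pass


# --------------------------------------------------------------------------- constants

def _expand_constants(text: str, consts: dict[str, str], depth: int = 0) -> str:
    if depth > 10:
        raise WorkflowError("constant expansion exceeded depth 10 (self-referential chain?)")

    def repl(m: re.Match) -> str:
        name = m.group(1)
        if name not in consts:
            raise WorkflowError(f"reference to undefined constant {name!r}")
        return consts[name]

    expanded = CONST_RE.sub(repl, text)
    if CONST_RE.search(expanded):
        return _expand_constants(expanded, consts, depth + 1)
    return expanded


def resolve_constants(spec: WorkflowSpec) -> WorkflowSpec:
    """Substitute every ``${NAME}`` reference; instance placeholders untouched.

    Idempotent: the output contains no ``${...}`` occurrences.
    """
    consts = spec.const_map

    def ex(text: str | None) -> str | None:
        return None if text is None else _expand_constants(text, consts)

    new_blocks = []
    for b in spec.blocks:
        if isinstance(b, blocks.FolderBlock):
            b = replace(b, folder=ex(b.folder), pattern=ex(b.pattern))
        elif isinstance(b, blocks.TableBlock):
            b = replace(b, table=ex(b.table))
        new_blocks.append(b)

    new_tasks = []
    for t in spec.tasks:
        new_tasks.append(
            replace(
                t,
                parameters=tuple((k, ex(v)) for k, v in t.parameters),
                stdout_path=ex(t.stdout_path),
                stderr_path=ex(t.stderr_path),
                env=tuple((k, ex(v)) for k, v in t.env),
                task_actions=tuple(
                    replace(a, src=ex(a.src), dst=ex(a.dst)) for a in t.task_actions
                ),
            )
        )
    return replace(spec, blocks=tuple(new_blocks), tasks=tuple(new_tasks))


# --------------------------------------------------------------------------- validation

def validate_workflow(spec: WorkflowSpec, registry: ModuleRegistry) -> list[Diagnostic]:
    """Static lint: type-check task parameters against their module descriptors.

    Returns an empty list iff the workflow is ready to run.  Values still
    containing constants or instance placeholders are only type-checked when
    fully literal.
    """
    diags: list[Diagnostic] = []
    for t in spec.tasks:
        try:
            module = registry.find(t.module_ref)
        except Exception as exc:
            diags.append(Diagnostic(t.id, str(exc)))
            continue
        pmap = module.param_map
        for pname, template in t.parameters:
            if pname not in pmap:
                diags.append(Diagnostic(t.id, f"unknown parameter {pname!r} for module "
                                              f"{module.module_name!r}"))
                continue
            if t.process_block_ref is None and blocks.has_placeholder(template):
                diags.append(
                    Diagnostic(t.id, f"parameter {pname!r} uses an instance placeholder "
                                     "but the task has no process block")
                )
                continue
            if blocks.has_placeholder(template) or CONST_RE.search(template):
                continue  # value known only per instance
            try:
                pmap[pname].parse_value(template)
            except Exception as exc:
                diags.append(Diagnostic(t.id, str(exc)))
        assigned = {p for p, _ in t.parameters}
        for p in module.params:
            if p.required and p.default is None and p.name not in assigned:
                diags.append(Diagnostic(t.id, f"required parameter {p.name!r} not assigned"))
        block_ref = t.process_block_ref
        if block_ref is not None:
            decl = spec.block_by_name(block_ref)
            if isinstance(decl, blocks.InputBlock) and not t.dependencies:
                diags.append(Diagnostic(t.id, "process input block requires >= 1 dependency"))
            if (
                isinstance(decl, blocks.InputBlock)
                and not decl.compare_by_index
                and len(t.dependencies) > 1
            ):
                diags.append(
                    Diagnostic(t.id, "input block over multiple dependencies requires "
                                     "compareByIndex='true'")
                )
    return diags


# --------------------------------------------------------------------------- serialization

def serialize_workflow(spec: WorkflowSpec) -> bytes:
    """Write a spec back into the workflow dialect (parse -> serialize -> parse
    is a fixed point under spec equality, modulo base_dir)."""
    root = etree.Element("watchdog")
    settings = etree.SubElement(root, "settings")
    if spec.constants:
        consts = etree.SubElement(settings, "constants")
        for k, v in spec.constants:
            etree.SubElement(consts, "const", name=k, value=v)
    if spec.executors:
        exes = etree.SubElement(settings, "executors")
        for e in spec.executors:
            attrs = {"name": e.name, "type": e.exec_type, "maxSlots": str(e.max_slots)}
            if e.default:
                attrs["default"] = "true"
            attrs.update(e.attr_map)
            etree.SubElement(exes, "executor", **attrs)
    if spec.blocks:
        pb = etree.SubElement(settings, "processBlock")
        for b in spec.blocks:
            _serialize_block(pb, b)
    if spec.module_folders:
        mf = etree.SubElement(settings, "moduleFolders")
        for p in spec.module_folders:
            etree.SubElement(mf, "folder", path=p)
    tasks = etree.SubElement(root, "tasks")
    for t in spec.tasks:
        _serialize_task(tasks, t)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _serialize_block(parent, b) -> None:
    if isinstance(b, blocks.SequenceBlock):
        etree.SubElement(parent, "processSequence", name=b.name,
                         start=_num(b.start), end=_num(b.end), step=_num(b.step))
    elif isinstance(b, blocks.FolderBlock):
        etree.SubElement(parent, "processFolder", name=b.name, folder=b.folder,
                         pattern=b.pattern)
    elif isinstance(b, blocks.TableBlock):
        etree.SubElement(parent, "processTable", name=b.name, table=b.table)
    elif isinstance(b, blocks.InputBlock):
        etree.SubElement(parent, "processInput", name=b.name,
                         compareByIndex="true" if b.compare_by_index else "false")
    else:
        raise WorkflowError(f"cannot serialize block declaration {type(b).__name__}")


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def _serialize_task(parent, t: TaskSpec) -> None:
    attrs = {"id": str(t.id), "name": t.name}
    if t.process_block_ref:
        attrs["processBlock"] = t.process_block_ref
    if t.executor_ref:
        attrs["executor"] = t.executor_ref
    if t.max_running is not None:
        attrs["maxRunning"] = str(t.max_running)
    if t.checkpoint:
        attrs["checkpoint"] = "true"
    el = etree.SubElement(parent, t.module_ref, **attrs)
    if t.parameters:
        par = etree.SubElement(el, "parameter")
        for k, v in t.parameters:
            sub = etree.SubElement(par, k)
            sub.text = v
    if t.dependencies:
        deps = etree.SubElement(el, "dependencies")
        for d in t.dependencies:
            sub = etree.SubElement(deps, "depends")
            if d.separate:
                sub.set("separate", "true")
            sub.text = d.target
    if t.stdout_path or t.stderr_path:
        streams = etree.SubElement(el, "streams")
        if t.stdout_path:
            etree.SubElement(streams, "stdout", path=t.stdout_path)
        if t.stderr_path:
            etree.SubElement(streams, "stderr", path=t.stderr_path)
    if t.env:
        envel = etree.SubElement(el, "environment")
        for k, v in t.env:
            etree.SubElement(envel, "var", name=k, value=v)
    if t.task_actions:
        actions = etree.SubElement(el, "actions")
        for a in t.task_actions:
            attrs = {"phase": a.phase, "type": a.action, "src": a.src}
            if a.dst:
                attrs["dst"] = a.dst
            etree.SubElement(actions, "action", **attrs)
    if t.checkers:
        checkers = etree.SubElement(el, "checkers")
        for c in t.checkers:
            args = ",".join(f"{typ}:{val}" for val, typ in c.ctor_args)
            attrs = {"name": c.checker_name, "kind": c.kind}
            if args:
                attrs["args"] = args
            etree.SubElement(checkers, "checker", **attrs)
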