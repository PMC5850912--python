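"""Process blocks: declarative generators of per-replicate task instances.

A process block turns one task declaration into many subtasks — one per
*instance*, where an instance is an ordered binding of variables.  Four block
types are built in:

* sequence — numeric for-loop (start, end, step),
* folder   — one instance per file matching a glob in a folder,
* table    — one instance per data row of a TSV file with a header,
* input    — instances derived from return values of upstream subtasks.

New block types can be registered at run time (:func:`register_block_type`).
Placeholders in parameter templates are substituted per instance:
``{}`` is the full value of a single-variable instance, ``[k]`` is the file
name of that value with its last *k* dot-suffixes stripped, ``{$var}`` is a
named variable.
"""

from __future__ import annotations

import csv
import logging
import math
import os
import re
from dataclasses import dataclass, field
from fnmatch import fnmatch
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .exceptions import BlockError, PlaceholderError

logger = logging.getLogger(__name__)

#: reserved variable name for single-variable blocks
VALUE_VAR = "value"


@dataclass(frozen=True)
class Instance:
    """One variable binding produced by a process block."""

    variables: tuple[tuple[str, str], ...]  # ordered (name, value) pairs
    origin: tuple[str, int, str | None] = ("", 1, None)  # (block, ordinal, source key)

    def __post_init__(self):
        if not self.variables:
            raise BlockError("an instance must carry at least one variable")

    @property
    def var_map(self) -> dict[str, str]:
        return dict(self.variables)

    @property
    def is_single(self) -> bool:
        return len(self.variables) == 1

    @property
    def value(self) -> str:
        if not self.is_single:
            raise BlockError("instance holds multiple variables; no single value")
        return self.variables[0][1]

    @property
    def ordinal(self) -> int:
        return self.origin[1]


def make_instance(
    variables: Mapping[str, str], block: str = "", ordinal: int = 1, source: str | None = None
) -> Instance:
    return Instance(tuple(variables.items()), (block, ordinal, source))


# --------------------------------------------------------------------------- declarations

@dataclass(frozen=True)
class SequenceBlock:
    name: str
    start: float
    end: float
    step: float = 1.0

    def __post_init__(self):
        for v in (self.start, self.end, self.step):
            if not math.isfinite(v):
                raise BlockError(f"block {self.name!r}: non-finite bound {v}")
        if self.step == 0:
            raise BlockError(f"block {self.name!r}: step must not be zero")
        if self.start != self.end and (self.end - self.start) * self.step < 0:
            raise BlockError(
                f"block {self.name!r}: step sign does not move start {self.start} toward end {self.end}"
            )


@dataclass(frozen=True)
class FolderBlock:
    name: str
    folder: str
    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise BlockError(f"block {self.name!r}: pattern must be non-empty")


@dataclass(frozen=True)
class TableBlock:
    name: str
    table: str


@dataclass(frozen=True)
class InputBlock:
    name: str
    compare_by_index: bool = False


# --------------------------------------------------------------------------- expansion

def expand_sequence(block: SequenceBlock) -> list[Instance]:
    """Numeric for-loop: start, start+step, ... up to and including end.

    Integral start/end/step render without a decimal point so values stay
    usable in file names.
    """
    integral = all(float(v).is_integer() for v in (block.start, block.end, block.step))
    # small tolerance so 0.1-style steps still hit the end bound
    n = int(math.floor((block.end - block.start) / block.step + 1e-9)) + 1
    out = []
    for i in range(max(n, 0)):
        v = block.start + i * block.step
        out.append(
            make_instance({VALUE_VAR: _fmt_number(v, integral)}, block.name, i + 1)
        )
    return out


def _fmt_number(v: float, integral: bool) -> str:
    if integral:
        return str(int(round(v)))
    return format(round(v, 10), "g")


def expand_folder(block: FolderBlock) -> list[Instance]:
    """One instance per regular file matching the glob; sorted by absolute path.

    No recursion into subfolders.  Zero matches is not an error: an empty list
    is returned and a warning logged.
    """
    folder = Path(block.folder)
    if not folder.is_dir():
        raise BlockError(f"block {block.name!r}: folder does not exist: {folder}")
    paths = sorted(
        str(p.resolve())
        for p in folder.iterdir()
        if p.is_file() and fnmatch(p.name, block.pattern)
    )
    if not paths:
        logger.warning("process folder %r matched no files in %s", block.name, folder)
    return [make_instance({VALUE_VAR: p}, block.name, i + 1) for i, p in enumerate(paths)]


def expand_table(block: TableBlock) -> list[Instance]:
    """One instance per data row of a TSV file; variables named by the header."""
    path = Path(block.table)
    if not path.exists():
        raise BlockError(f"block {block.name!r}: table does not exist: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r != []]
    if not rows:
        raise BlockError(f"block {block.name!r}: table {path} is empty")
    header = rows[0]
    if len(set(header)) != len(header):
        raise BlockError(f"block {block.name!r}: duplicate column name in header {header}")
    out = []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise BlockError(
                f"block {block.name!r}: row {i} has {len(row)} cells, header has {len(header)}"
            )
        out.append(make_instance(dict(zip(header, row)), block.name, i))
    if not out:
        logger.warning("process table %r has a header but no data rows", block.name)
    return out


def expand_input(dep_records: Sequence, block_name: str = "") -> list[Instance]:
    """Instances from the return values of finished upstream subtasks.

    One instance per record, ordered by the source subtask index; every record
    must expose the same variable set.
    """
    records = sorted(dep_records, key=lambda r: (r.task_id, r.subtask_index))
    instances = []
    ref_vars: tuple[str, ...] | None = None
    for i, rec in enumerate(records, start=1):
        if rec.state.name not in ("SUCCEEDED", "RESOLVED_MANUAL"):
            raise BlockError(
                f"input block {block_name!r}: subtask {rec.task_id}-{rec.subtask_index} "
                f"is not terminal-successful ({rec.state.name})"
            )
        if not rec.return_values:
            raise BlockError(
                f"input block {block_name!r}: subtask {rec.task_id}-{rec.subtask_index} "
                "returned no values"
            )
        names = tuple(rec.return_values)
        if ref_vars is None:
            ref_vars = names
        elif set(names) != set(ref_vars):
            raise BlockError(
                f"input block {block_name!r}: conflicting variable sets "
                f"{sorted(ref_vars)} vs {sorted(names)}"
            )
        instances.append(
            make_instance(
                rec.return_values, block_name, i, source=f"{rec.task_id}-{rec.subtask_index}"
            )
        )
    return instances


# --------------------------------------------------------------------------- placeholders

_PLACEHOLDER_RE = re.compile(r"\{\}|\[(\d+)\]|\{\$([A-Za-z_][A-Za-z0-9_]*)\}")


def substitute_placeholders(template: str, instance: Instance) -> str:
    """Replace instance placeholders in a template string.

    ``{}`` and ``[k]`` require a single-variable instance; ``[k]`` takes the
    base file name of the value and strips its last *k* dot-suffixes (k >= 1).
    Text without placeholders is returned unchanged, so the substitution is
    idempotent on its own output as long as variable values contain no
    placeholder syntax.
    """

    def repl(m: re.Match) -> str:
        if m.group(0) == "{}":
            return instance.value  # raises on multi-variable instances
        if m.group(1) is not None:
            k = int(m.group(1))
            if k < 1:
                raise PlaceholderError(f"[{k}]: suffix count must be >= 1")
            base = os.path.basename(instance.value)
            parts = base.split(".")
            if len(parts) <= k:
                raise PlaceholderError(
                    f"[{k}]: {base!r} has fewer than {k} dot-suffixes"
                )
            return ".".join(parts[:-k])
        var = m.group(2)
        vmap = instance.var_map
        if var not in vmap:
            raise PlaceholderError(f"unknown instance variable {var!r}")
        return vmap[var]

    try:
        return _PLACEHOLDER_RE.sub(repl, template)
    except BlockError as exc:  # {} on multi-variable instance
        raise PlaceholderError(str(exc)) from exc


def has_placeholder(template: str) -> bool:
    return _PLACEHOLDER_RE.search(template) is not None


# --------------------------------------------------------------------------- plugin registry

#: element name -> (attribute parser, expander).  The parser receives the XML
#: attribute map and returns a block declaration; the expander turns that
#: declaration into a list of instances with stable 1..N ordinals.
_BLOCK_TYPES: dict[str, tuple[Callable[[Mapping[str, str]], object],
                              Callable[[object], list[Instance]]]] = {}


def register_block_type(element_name, parser, expander) -> None:
    """Register a new process-block element usable in workflow settings."""
    _BLOCK_TYPES[element_name] = (parser, expander)


def block_types() -> dict:
    return dict(_BLOCK_TYPES)


def parse_block_element(tag: str, attrs: Mapping[str, str]):
    if tag not in _BLOCK_TYPES:
        raise BlockError(f"unknown process block element <{tag}>")
    return _BLOCK_TYPES[tag][0](attrs)


def expand_block(decl) -> list[Instance]:
    """Expand any registered non-input block declaration."""
    for tag, (_parser, expander) in _BLOCK_TYPES.items():
        if expander is not None and _matches(decl, tag):
            return expander(decl)
    raise BlockError(f"no expander registered for block declaration {type(decl).__name__}")


def _matches(decl, tag: str) -> bool:
    return getattr(decl, "_element_tag", None) == tag or _DEFAULT_TAGS.get(type(decl)) == tag


def _req(attrs: Mapping[str, str], key: str, tag: str) -> str:
    if key not in attrs:
        raise BlockError(f"<{tag}> requires attribute {key!r}")
    return attrs[key]


def _parse_sequence(attrs):
    return SequenceBlock(
        name=_req(attrs, "name", "processSequence"),
        start=float(_req(attrs, "start", "processSequence")),
        end=float(_req(attrs, "end", "processSequence")),
        step=float(attrs.get("step", "1")),
    )


def _parse_folder(attrs):
    return FolderBlock(
        name=_req(attrs, "name", "processFolder"),
        folder=_req(attrs, "folder", "processFolder"),
        pattern=_req(attrs, "pattern", "processFolder"),
    )


def _parse_table(attrs):
    return TableBlock(
        name=_req(attrs, "name", "processTable"),
        table=_req(attrs, "table", "processTable"),
    )


def _parse_input(attrs):
    raw = attrs.get("compareByIndex", "false").lower()
    return InputBlock(
        name=_req(attrs, "name", "processInput"),
        compare_by_index=raw in ("true", "1", "yes"),
    )


_DEFAULT_TAGS = {
    SequenceBlock: "processSequence",
    FolderBlock: "processFolder",
    TableBlock: "processTable",
    InputBlock: "processInput",
}

register_block_type("processSequence", _parse_sequence, expand_sequence)
register_block_type("processFolder", _parse_folder, expand_folder)
register_block_type("processTable", _parse_table, expand_table)
register_block_type("processInput", _parse_input, None)  # expansion is scheduler-driven
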