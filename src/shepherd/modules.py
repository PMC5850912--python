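"""Module descriptors: typed wrappers around command-line programs.

A *module* is a folder holding one ``<name>.module.xml`` descriptor plus any
scripts the wrapped program needs.  The descriptor declares the command to
execute, its parameters (name, type, valid range, occurrence counts) and any
return parameters the command exposes to downstream process-input blocks.

Parameter values are rendered into GNU-style argv: ``--name value`` per
occurrence, a bare ``--name`` for a set flag.
"""

from __future__ import annotations

import shlex
import stat
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .exceptions import ModuleError

PARAM_TYPES = ("string", "integer", "double", "file", "folder", "flag", "enum")
RETURN_TYPES = ("string", "integer", "double", "boolean")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


@dataclass(frozen=True)
class ParamDef:
    """One declared parameter of a module.

    ``min_occurs``/``max_occurs`` bound how many values may be assigned;
    ``required`` is equivalent to ``min_occurs >= 1`` and both views are kept
    consistent at construction time.
    """

    name: str
    value_type: str = "string"
    required: bool = False
    default: str | None = None
    numeric_range: tuple[float, float] | None = None
    enum_values: tuple[str, ...] | None = None
    min_occurs: int | None = None
    max_occurs: int | None = None

    def __post_init__(self):
        if not self.name:
            raise ModuleError("parameter name must be non-empty")
        if self.value_type not in PARAM_TYPES:
            raise ModuleError(f"unknown value type {self.value_type!r} for parameter {self.name!r}")
        if self.numeric_range is not None:
            if self.value_type not in ("integer", "double"):
                raise ModuleError(f"range given for non-numeric parameter {self.name!r}")
            lo, hi = self.numeric_range
            if lo > hi:
                raise ModuleError(f"parameter {self.name!r}: range min {lo} > max {hi}")
        if self.value_type == "enum" and not self.enum_values:
            raise ModuleError(f"enum parameter {self.name!r} declares no values")
        if self.value_type == "flag":
            if self.numeric_range is not None or self.enum_values:
                raise ModuleError(f"flag parameter {self.name!r} cannot carry a range or enum")
            if self.default is not None and self.default not in _TRUE | _FALSE:
                raise ModuleError(f"flag parameter {self.name!r}: default must be boolean-like")
        # reconcile required <-> min_occurs
        mn = self.min_occurs
        if mn is None:
            mn = 1 if self.required else 0
        mx = self.max_occurs
        if mx is None:
            mx = max(1, mn)
        if mn < 0 or mx < 0:
            raise ModuleError(f"parameter {self.name!r}: occurrence counts must be non-negative")
        if mn > mx:
            raise ModuleError(f"parameter {self.name!r}: minOccurs {mn} > maxOccurs {mx}")
        if self.required != (mn >= 1):
            raise ModuleError(
                f"parameter {self.name!r}: required={self.required} conflicts with minOccurs={mn}"
            )
        object.__setattr__(self, "min_occurs", mn)
        object.__setattr__(self, "max_occurs", mx)

    def parse_value(self, raw: str) -> str:
        """Validate one raw value against the declared type; return it unchanged."""
        t = self.value_type
        if t == "integer":
            try:
                v = int(raw)
            except ValueError:
                raise ModuleError(f"parameter {self.name!r}: {raw!r} is not an integer") from None
            self._check_range(v)
        elif t == "double":
            try:
                v = float(raw)
            except ValueError:
                raise ModuleError(f"parameter {self.name!r}: {raw!r} is not a number") from None
            self._check_range(v)
        elif t == "enum":
            if raw not in self.enum_values:
                raise ModuleError(
                    f"parameter {self.name!r}: {raw!r} not in {sorted(self.enum_values)}"
                )
        elif t == "flag":
            if raw.lower() not in _TRUE | _FALSE:
                raise ModuleError(f"flag parameter {self.name!r}: {raw!r} is not boolean-like")
        # string/file/folder accept any text
        return raw

    def _check_range(self, v: float) -> None:
        if self.numeric_range is not None:
            lo, hi = self.numeric_range
            if not (lo <= v <= hi):
                raise ModuleError(
                    f"parameter {self.name!r}: value {v} outside range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class ReturnParamDef:
    """A key the wrapped command reports back through its return file."""

    name: str
    value_type: str = "string"

    def __post_init__(self):
        if not self.name:
            raise ModuleError("return parameter name must be non-empty")
        if self.value_type not in RETURN_TYPES:
            raise ModuleError(f"unknown return type {self.value_type!r} for {self.name!r}")

    def parse_value(self, raw: str) -> str:
        t = self.value_type
        try:
            if t == "integer":
                int(raw)
            elif t == "double":
                float(raw)
            elif t == "boolean":
                if raw.lower() not in _TRUE | _FALSE:
                    raise ValueError
        except ValueError:
            raise ModuleError(f"return parameter {self.name!r}: {raw!r} is not a {t}") from None
        return raw


@dataclass(frozen=True)
class ModuleDescriptor:
    module_name: str
    command: tuple[str, ...]
    params: tuple[ParamDef, ...] = ()
    returns: tuple[ReturnParamDef, ...] = ()
    module_dir: Path | None = None

    def __post_init__(self):
        if not self.module_name:
            raise ModuleError("module name must be non-empty")
        if not self.command or not self.command[0]:
            raise ModuleError(f"module {self.module_name!r}: command must be non-empty")
        seen = set()
        for p in self.params:
            if p.name in seen:
                raise ModuleError(f"module {self.module_name!r}: duplicate parameter {p.name!r}")
            seen.add(p.name)
        rseen = set()
        for r in self.returns:
            if r.name in rseen:
                raise ModuleError(f"module {self.module_name!r}: duplicate return {r.name!r}")
            rseen.add(r.name)

    @property
    def param_map(self) -> dict[str, ParamDef]:
        return {p.name: p for p in self.params}

    @property
    def return_map(self) -> dict[str, ReturnParamDef]:
        return {r.name: r for r in self.returns}

    def resolved_command(self) -> list[str]:
        """Command argv with the executable resolved against the module folder.

        A relative executable that exists inside the module directory is made
        absolute so workflows can be run from any working directory.
        """
        argv = list(self.command)
        if self.module_dir is not None and not Path(argv[0]).is_absolute():
            cand = self.module_dir / argv[0]
            if cand.exists():
                argv[0] = str(cand)
        return argv


def _parse_bool(raw: str | None, default: bool = False) -> bool:
    if raw is None:
        return default
    if raw.lower() in _TRUE:
        return True
    if raw.lower() in _FALSE:
        return False
    raise ModuleError(f"invalid boolean attribute value {raw!r}")


def load_module(descriptor_path: str | Path) -> ModuleDescriptor:
    """Load and validate a module descriptor XML file."""
    path = Path(descriptor_path)
    if path.is_dir():
        candidates = sorted(path.glob("*.module.xml"))
        if len(candidates) != 1:
            raise ModuleError(f"{path}: expected exactly one *.module.xml, found {len(candidates)}")
        path = candidates[0]
    if not path.exists():
        raise ModuleError(f"module descriptor not found: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ModuleError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "module":
        raise ModuleError(f"{path}: root element must be <module>, got <{root.tag}>")
    name = root.get("name")
    command_attr = root.get("command")
    if not name or not command_attr:
        raise ModuleError(f"{path}: <module> requires non-empty 'name' and 'command' attributes")
    params: list[ParamDef] = []
    returns: list[ReturnParamDef] = []
    for child in root:
        if child.tag is etree.Comment:
            continue
        if child.tag == "param":
            params.append(_param_from_element(child, path))
        elif child.tag == "return":
            rname = child.get("name")
            if rname is None:
                raise ModuleError(f"{path}: <return> requires a 'name' attribute")
            returns.append(ReturnParamDef(rname, child.get("type", "string")))
        else:
            raise ModuleError(f"{path}: unknown element <{child.tag}> in module descriptor")
    return ModuleDescriptor(
        module_name=name,
        command=tuple(shlex.split(command_attr)),
        params=tuple(params),
        returns=tuple(returns),
        module_dir=path.parent.resolve(),
    )


def _param_from_element(el, path: Path) -> ParamDef:
    name = el.get("name")
    if name is None:
        raise ModuleError(f"{path}: <param> requires a 'name' attribute")
    rng = None
    if el.get("min") is not None or el.get("max") is not None:
        if el.get("min") is None or el.get("max") is None:
            raise ModuleError(f"{path}: parameter {name!r}: both 'min' and 'max' must be given")
        rng = (float(el.get("min")), float(el.get("max")))
    enum = None
    if el.get("enum") is not None:
        enum = tuple(v.strip() for v in el.get("enum").split(",") if v.strip())
    occurs = {}
    if el.get("minOccurs") is not None:
        occurs["min_occurs"] = int(el.get("minOccurs"))
    if el.get("maxOccurs") is not None:
        occurs["max_occurs"] = int(el.get("maxOccurs"))
    required = _parse_bool(el.get("required"), default=occurs.get("min_occurs", 0) >= 1)
    return ParamDef(
        name=name,
        value_type=el.get("type", "string"),
        required=required,
        default=el.get("default"),
        numeric_range=rng,
        enum_values=enum,
        **occurs,
    )


def render_command(
    descriptor: ModuleDescriptor,
    assignments: Mapping[str, Sequence[str] | str],
) -> list[str]:
    """Render validated parameter assignments into an argv list.

    Output is the module command followed by one ``--name value`` pair per
    occurrence, in descriptor declaration order (so permuting the assignment
    map never changes the result).  Flags render as a bare ``--name`` when set.
    Optional parameters with a default are rendered with that default when
    unassigned; optional parameters without one are omitted.
    """
    known = descriptor.param_map
    norm: dict[str, list[str]] = {}
    for key, val in assignments.items():
        if key not in known:
            raise ModuleError(f"module {descriptor.module_name!r}: unknown parameter {key!r}")
        norm[key] = [val] if isinstance(val, str) else list(val)

    argv = descriptor.resolved_command()
    for p in descriptor.params:
        values = norm.get(p.name)
        if values is None and p.default is not None:
            values = [p.default]
        if values is None:
            if p.required:
                raise ModuleError(
                    f"module {descriptor.module_name!r}: missing required parameter {p.name!r}"
                )
            continue
        if p.value_type == "flag":
            if len(values) != 1:
                raise ModuleError(f"flag parameter {p.name!r} takes a single boolean value")
            if p.parse_value(values[0]).lower() in _TRUE:
                argv.append(f"--{p.name}")
            continue
        if not (p.min_occurs <= len(values) <= p.max_occurs):
            raise ModuleError(
                f"parameter {p.name!r}: {len(values)} value(s) given, "
                f"allowed {p.min_occurs}..{p.max_occurs}"
            )
        for v in values:
            p.parse_value(v)
            argv.extend([f"--{p.name}", v])
    return argv


def descriptor_to_xml(descriptor: ModuleDescriptor) -> bytes:
    """Serialize a descriptor into the module XML dialect."""
    root = etree.Element(
        "module", name=descriptor.module_name, command=shlex.join(descriptor.command)
    )
    for p in descriptor.params:
        attrs = {"name": p.name, "type": p.value_type}
        if p.required:
            attrs["required"] = "true"
        if p.default is not None:
            attrs["default"] = p.default
        if p.numeric_range is not None:
            attrs["min"] = _fmt_num(p.numeric_range[0])
            attrs["max"] = _fmt_num(p.numeric_range[1])
        if p.enum_values:
            attrs["enum"] = ",".join(p.enum_values)
        if p.min_occurs not in (0, 1) or p.max_occurs != max(1, p.min_occurs):
            attrs["minOccurs"] = str(p.min_occurs)
            attrs["maxOccurs"] = str(p.max_occurs)
        etree.SubElement(root, "param", **attrs)
    for r in descriptor.returns:
        etree.SubElement(root, "return", name=r.name, type=r.value_type)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


_SKELETON = """\
#!/bin/sh
# Skeleton wrapper generated by `shepherd scaffold-module`.
# Parses the declared --name value arguments; extend it with the real
# program call.  Return parameters go to "$WATCHDOG_RETURN_FILE" as
# key<TAB>value lines.
set -eu
{vars}
while [ $# -gt 0 ]; do
    case "$1" in
{cases}
        *) echo "unknown argument: $1" >&2; exit 64 ;;
    esac
done
{body}
exit 0
"""


def scaffold_module(
    name: str,
    param_specs: Iterable[ParamDef] = (),
    with_skeleton: bool = False,
    dest_dir: str | Path = ".",
    returns: Iterable[ReturnParamDef] = (),
    command: Sequence[str] | None = None,
    body: str = ": # program call goes here",
) -> Path:
    """Write a new module folder (descriptor + optional skeleton script).

    Returns the created folder path.  The folder must not already exist; on
    invalid input nothing is written.  The result round-trips through
    :func:`load_module`.
    """
    params = tuple(param_specs)
    rets = tuple(returns)
    if command is None:
        command = (f"./{name}.sh",) if with_skeleton else ("true",)
    folder = Path(dest_dir) / name
    if folder.exists():
        raise ModuleError(f"module folder already exists: {folder}")
    # validate before any write
    descriptor = ModuleDescriptor(
        module_name=name, command=tuple(command), params=params, returns=rets
    )
    folder.mkdir(parents=True)
    (folder / f"{name}.module.xml").write_bytes(descriptor_to_xml(descriptor))
    if with_skeleton:
        script = folder / f"{name}.sh"
        script.write_text(_render_skeleton(descriptor, body))
        script.chmod(script.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
    return folder


def _render_skeleton(descriptor: ModuleDescriptor, body: str) -> str:
    var_lines, case_lines = [], []
    for p in descriptor.params:
        var_lines.append(f"{p.name}=''")
        if p.value_type == "flag":
            case_lines.append(f'        --{p.name}) {p.name}=true; shift ;;')
        else:
            case_lines.append(f'        --{p.name}) {p.name}="$2"; shift 2 ;;')
    return _SKELETON.format(
        vars="\n".join(var_lines) or ": # no parameters",
        cases="\n".join(case_lines) or '        --*) shift 2 ;;',
        body=body,
    )


class ModuleRegistry:
    """Maps workflow task element names to module descriptors.

    Searches an ordered list of module folders; the first folder containing a
    module with the requested name wins.
    """

    def __init__(self, search_paths: Iterable[str | Path] = ()):
        self.search_paths: list[Path] = [Path(p) for p in search_paths]
        self._cache: dict[str, ModuleDescriptor] = {}

    def add_search_path(self, path: str | Path, front: bool = False) -> None:
        p = Path(path)
        if front:
            self.search_paths.insert(0, p)
        else:
            self.search_paths.append(p)
        self._cache.clear()

    def register(self, descriptor: ModuleDescriptor) -> None:
        """Register an in-memory descriptor (used by tests and plugins)."""
        self._cache[descriptor.module_name] = descriptor

    def find(self, module_name: str) -> ModuleDescriptor:
        if module_name in self._cache:
            return self._cache[module_name]
        for base in self.search_paths:
            cand = base / module_name / f"{module_name}.module.xml"
            if cand.exists():
                desc = load_module(cand)
                if desc.module_name != module_name:
                    raise ModuleError(
                        f"{cand}: descriptor name {desc.module_name!r} != folder {module_name!r}"
                    )
                self._cache[module_name] = desc
                return desc
        raise ModuleError(f"no module named {module_name!r} in {self.search_paths}")

    def __contains__(self, module_name: str) -> bool:
        try:
            self.find(module_name)
            return True
        except ModuleError:
            return False
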