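"""Success/error judgment of finished subtasks.

The base rule is the exit code: zero means success, anything else failure.
Because many tools exit zero regardless of outcome, a task may additionally
declare ordered *checkers* — small predicates over the finished subtask's
artifacts (stdout/stderr, files it promised to write).  Each checker states an
expectation; a success-kind checker votes success when its expectation holds,
an error-kind checker votes error when it is violated.  Any error vote (or a
nonzero exit) makes the final verdict FAILURE — when both success and error
are detected the subtask is treated as failed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .exceptions import CheckerError, TransitionError
from .modules import ModuleDescriptor

ARG_TYPES = ("string", "integer", "double", "boolean")


@dataclass(frozen=True)
class CheckerDecl:
    checker_name: str
    kind: str  # "success" | "error"
    ctor_args: tuple[tuple[str, str], ...] = ()  # (value, type) pairs
    order: int = 0

    def __post_init__(self):
        if self.kind not in ("success", "error"):
            raise CheckerError(f"checker {self.checker_name!r}: kind must be success or error")
        for value, typ in self.ctor_args:
            if typ not in ARG_TYPES:
                raise CheckerError(f"checker {self.checker_name!r}: unknown arg type {typ!r}")
            _parse_arg(value, typ)  # validate eagerly

    def typed_args(self) -> list:
        return [_parse_arg(v, t) for v, t in self.ctor_args]


def _parse_arg(value: str, typ: str):
    try:
        if typ == "integer":
            return int(value)
        if typ == "double":
            return float(value)
        if typ == "boolean":
            low = value.lower()
            if low in ("true", "1", "yes"):
                return True
            if low in ("false", "0", "no"):
                return False
            raise ValueError(value)
        return value
    except ValueError:
        raise CheckerError(f"checker argument {value!r} is not a valid {typ}") from None


@dataclass(frozen=True)
class Artifacts:
    """Paths a checker may inspect after a subtask finished."""

    stdout_path: str | None = None
    stderr_path: str | None = None
    return_file: str | None = None


@dataclass
class Verdict:
    success_votes: int = 0
    error_votes: int = 0
    messages: list[str] = field(default_factory=list)
    final: str = "SUCCESS"  # "SUCCESS" | "FAILURE"


def judge_exit(exit_code: int | None) -> tuple[bool, str | None]:
    """Base judgment: exit code zero is success; anything else is failure."""
    if exit_code == 0:
        return True, None
    return False, f"command exited with code {exit_code}"


def judge_result(
    record,
    checkers: Sequence[CheckerDecl],
    artifacts: Artifacts,
) -> Verdict:
    """Combine the exit-code judgment with ordered custom checkers.

    Checkers run in declaration order; their order affects only message order,
    never the final verdict.  A checker that cannot be instantiated counts as
    an error vote carrying the failure message.
    """
    verdict = Verdict()
    base_ok, base_msg = judge_exit(record.exit_code)
    if base_msg:
        verdict.messages.append(base_msg)
    for decl in sorted(checkers, key=lambda c: c.order):
        try:
            checker = instantiate_checker(decl)
            ok, msg = checker(record, artifacts)
        except Exception as exc:  # instantiation or evaluation failure
            verdict.error_votes += 1
            verdict.messages.append(f"checker {decl.checker_name!r} failed: {exc}")
            continue
        if decl.kind == "success" and ok:
            verdict.success_votes += 1
        elif decl.kind == "error" and not ok:
            verdict.error_votes += 1
        if msg:
            verdict.messages.append(f"{decl.checker_name}: {msg}")
    verdict.final = "SUCCESS" if base_ok and verdict.error_votes == 0 else "FAILURE"
    if verdict.final == "FAILURE" and not verdict.messages:
        verdict.messages.append("failure detected by checker votes")
    return verdict


# --------------------------------------------------------------------------- registry

#: name -> factory(*typed_args) -> callable(record, artifacts) -> (ok, message)
_CHECKERS: dict[str, Callable] = {}


def register_checker(name: str, factory: Callable) -> None:
    _CHECKERS[name] = factory


def instantiate_checker(decl: CheckerDecl):
    if decl.checker_name not in _CHECKERS:
        raise CheckerError(f"no checker registered under {decl.checker_name!r}")
    return _CHECKERS[decl.checker_name](*decl.typed_args())


def _read_text(path: str | None) -> str:
    if not path or not Path(path).exists():
        return ""
    return Path(path).read_text(errors="replace")


def _stderr_pattern(pattern: str, max_hits: int = 0):
    """Expectation: at most `max_hits` regex matches in the captured stderr."""
    rx = re.compile(pattern)

    def check(record, artifacts):
        hits = len(rx.findall(_read_text(artifacts.stderr_path)))
        ok = hits <= max_hits
        return ok, f"{hits} match(es) of /{pattern}/ in stderr (allowed {max_hits})"

    return check


def _file_exists(path: str):
    """Expectation: the given file exists when the subtask finishes."""

    def check(record, artifacts):
        ok = Path(path).exists()
        return ok, None if ok else f"expected file missing: {path}"

    return check


def _min_file_size(path: str, min_bytes: int):
    """Expectation: the file exists and holds at least `min_bytes` bytes."""

    def check(record, artifacts):
        p = Path(path)
        size = p.stat().st_size if p.exists() else -1
        ok = size >= min_bytes
        return ok, None if ok else f"{path}: {max(size, 0)} bytes < required {min_bytes}"

    return check


register_checker("stderr_pattern", _stderr_pattern)
register_checker("file_exists", _file_exists)
register_checker("min_file_size", _min_file_size)


def resolve_manually(record, user_returns: dict[str, str], module: ModuleDescriptor):
    """Mark a failed subtask as manually resolved with user-supplied returns.

    The supplied values must cover exactly the module's declared return
    parameters and type-check against them; downstream process-input blocks
    then consume them as if the subtask had succeeded.
    """
    from .scheduler import SubtaskState, apply_transition

    if record.state is not SubtaskState.FAILED_AWAITING_USER:
        raise TransitionError(
            f"subtask {record.task_id}-{record.subtask_index} is {record.state.name}, "
            "only FAILED_AWAITING_USER can be resolved manually"
        )
    declared = module.return_map
    missing = set(declared) - set(user_returns)
    extra = set(user_returns) - set(declared)
    if missing or extra:
        raise CheckerError(
            f"manual returns must match declared return parameters exactly; "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    for name, value in user_returns.items():
        try:
            declared[name].parse_value(value)
        except Exception as exc:
            raise CheckerError(str(exc)) from exc
    return apply_transition(record, "user_resolve", return_values=dict(user_returns))
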