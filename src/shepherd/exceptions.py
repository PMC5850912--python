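"""Exception hierarchy for the workflow engine."""


class ShepherdError(Exception):
    """Base class for all engine errors."""


class ModuleError(ShepherdError):
    """Invalid module descriptor or parameter assignment."""


class WorkflowError(ShepherdError):
    """Workflow file cannot be parsed into a valid specification."""


class BlockError(ShepherdError):
    """Process block declaration or expansion failure."""


class PlaceholderError(BlockError):
    """Malformed or unsatisfiable instance placeholder in a template."""


class TransitionError(ShepherdError):
    """Illegal subtask lifecycle transition."""


class SchedulerError(ShepherdError):
    """Scheduling failure (unresolvable reference, inconsistent state)."""


class DeadlockError(SchedulerError):
    """No subtask can make progress and no user action is pending.

    Carries the set of blocked (task_id, subtask_index) keys.
    """

    def __init__(self, message: str, blocked: set | None = None):
        super().__init__(message)
        self.blocked = blocked or set()


class ExecutorError(ShepherdError):
    """Executor cannot run a command (misconfiguration, stub backend)."""


class TaskActionError(ShepherdError):
    """A before/after task action failed."""


class CheckerError(ShepherdError):
    """Error-checker declaration or manual resolution is invalid."""
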