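import pytest
from hypothesis import HealthCheck, settings

from shepherd.modules import ModuleDescriptor, ModuleRegistry, ParamDef, ReturnParamDef
from shepherd.workflow import DependencyDecl, TaskSpec, WorkflowSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def registry() -> ModuleRegistry:
    """In-memory registry with a few generic modules."""
    reg = ModuleRegistry()
    reg.register(ModuleDescriptor("noopTask", ("true",)))
    reg.register(
        ModuleDescriptor(
            "echoTask", ("echo",), params=(ParamDef("value", "string", required=True),)
        )
    )
    reg.register(
        ModuleDescriptor(
            "retTask", ("true",),
            params=(ParamDef("input", "string"),),
            returns=(ReturnParamDef("file"), ReturnParamDef("fCount", "integer")),
        )
    )
    reg.register(
        ModuleDescriptor(
            "sleepTask", ("sleep-module.sh",),
            params=(ParamDef("wait", "integer", required=True),),
        )
    )
    return reg


def chain_spec(n: int = 3, **task_kwargs) -> WorkflowSpec:
    """Linear workflow 1 -> 2 -> ... -> n of no-op tasks."""
    tasks = []
    for i in range(1, n + 1):
        deps = (DependencyDecl(str(i - 1)),) if i > 1 else ()
        tasks.append(
            TaskSpec(id=i, name=f"t{i}", module_ref="noopTask", dependencies=deps,
                     **task_kwargs)
        )
    return WorkflowSpec(tasks=tuple(tasks))


@pytest.fixture
def chain():
    return chain_spec(3)
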