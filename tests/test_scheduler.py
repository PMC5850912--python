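"""Dependency resolution, lifecycle transitions, concurrency, resume, recovery."""

import pytest

from conftest import chain_spec
from shepherd.blocks import InputBlock, SequenceBlock
from shepherd.exceptions import DeadlockError, SchedulerError, TransitionError
from shepherd.executors import VirtualExecutorConfig
from shepherd.modules import ModuleDescriptor, ParamDef
from shepherd.scheduler import (
    Engine,
    ExecutionTrace,
    ScopeFilter,
    SubtaskRecord,
    SubtaskState as S,
    apply_scope,
    apply_transition,
    build_graph,
)
from shepherd.workflow import DependencyDecl, ExecutorDecl, TaskSpec, WorkflowSpec


def engine(spec, registry, tmp_path, **kwargs):
    return Engine(spec, registry, workdir=tmp_path / "scratch", dry_run=True, **kwargs)


def barrier_spec():
    """B depends (task-level) on A1, A2 (3 subtasks) and A3."""
    return WorkflowSpec(
        executors=(ExecutorDecl(name="v", exec_type="virtual", max_slots=8, default=True,
                                attributes=(("hosts", "1"), ("slotsPerHost", "8"))),),
        blocks=(SequenceBlock("triple", 1, 3, 1),),
        tasks=(
            TaskSpec(id=1, name="A1", module_ref="noopTask"),
            TaskSpec(id=2, name="A2", module_ref="echoTask", process_block_ref="triple",
                     parameters=(("value", "{}"),)),
            TaskSpec(id=3, name="A3", module_ref="noopTask"),
            TaskSpec(id=4, name="B", module_ref="noopTask",
                     dependencies=(DependencyDecl("1"), DependencyDecl("2"),
                                   DependencyDecl("3"))),
        ),
    )


def pipeline_spec(separate=True):
    """A (3 subtasks, serialized) feeding B via a process input block."""
    return WorkflowSpec(
        executors=(ExecutorDecl(name="v", exec_type="virtual", max_slots=8, default=True,
                                attributes=(("hosts", "1"), ("slotsPerHost", "8"))),),
        blocks=(SequenceBlock("triple", 1, 3, 1), InputBlock("inp")),
        tasks=(
            TaskSpec(id=1, name="A", module_ref="retTask", process_block_ref="triple",
                     max_running=1, parameters=(("input", "{}"),)),
            TaskSpec(id=2, name="B", module_ref="noopTask", process_block_ref="inp",
                     dependencies=(DependencyDecl("1", separate=separate),)),
        ),
    )


class TestGraphAndScope:
    def test_barrier_graph_edges_and_frontier(self, registry):
        g = build_graph(barrier_spec())
        assert set(g.predecessors(4)) == {1, 2, 3}
        frontier = {n for n in g if g.in_degree(n) == 0}
        assert frontier == {1, 2, 3}

    def test_chain_frontier(self):
        g = build_graph(chain_spec(3))
        assert {n for n in g if g.in_degree(n) == 0} == {1}

    @pytest.mark.parametrize(
        "filt, expected",
        [
            (None, {1, 2, 3}),
            (ScopeFilter(start="2"), {2, 3}),
            (ScopeFilter(stop="2"), {1, 2}),
            (ScopeFilter(exclude=("2",)), {1, 3}),
            (ScopeFilter(start="2", exclude=("3",)), {2}),
            (ScopeFilter(start="3", include=("1",)), {1, 3}),
        ],
    )
    def test_scope_rules(self, filt, expected):
        assert apply_scope(chain_spec(3), filt) == expected

    def test_start_task_runs_immediately(self, registry, tmp_path):
        eng = engine(chain_spec(3), registry, tmp_path, scope=ScopeFilter(start="2"))
        recs, trace = eng.run()
        assert recs[(1, 0)].state is S.EXCLUDED
        assert trace.first(2, 0, "running").time == 0.0
        assert recs[(3, 0)].state is S.SUCCEEDED

    def test_include_exclude_overlap_rejected(self):
        with pytest.raises(SchedulerError, match="overlap"):
            apply_scope(chain_spec(3), ScopeFilter(include=("2",), exclude=("2",)))


class TestTransitions:
    def test_full_success_path(self):
        rec = SubtaskRecord(1, 1)
        for event in ("ready", "launch", "succeed"):
            apply_transition(rec, event)
        assert rec.state is S.SUCCEEDED

    def test_restart_increments_attempt(self):
        rec = SubtaskRecord(1, 1, state=S.FAILED_AWAITING_USER)
        apply_transition(rec, "user_restart")
        assert rec.state is S.READY and rec.attempt == 2

    def test_resolve_sets_returns(self):
        rec = SubtaskRecord(1, 1, state=S.FAILED_AWAITING_USER)
        apply_transition(rec, "user_resolve", return_values={"file": "/x"})
        assert rec.state is S.RESOLVED_MANUAL and rec.return_values == {"file": "/x"}

    @pytest.mark.parametrize(
        "state, event",
        [
            (S.SUCCEEDED, "launch"),
            (S.PENDING, "launch"),
            (S.RUNNING, "user_ignore"),
            (S.IGNORED, "user_restart"),
            (S.RESOLVED_MANUAL, "fail"),
        ],
    )
    def test_illegal_edges_rejected(self, state, event):
        with pytest.raises(TransitionError):
            apply_transition(SubtaskRecord(1, 1, state=state), event)


class TestBarrierAndPipelining:
    def test_task_level_barrier_waits_for_all_five(self, registry, tmp_path):
        eng = engine(barrier_spec(), registry, tmp_path)
        recs, trace = eng.run()
        b_start = trace.first(4, 0, "running").time
        upstream_done = [e.time for e in trace.by_transition("succeeded")
                         if e.task_id in (1, 2, 3)]
        assert len(upstream_done) == 5
        assert b_start >= max(upstream_done)

    def test_subtask_pipelining_starts_before_upstream_finishes(self, registry, tmp_path):
        eng = engine(pipeline_spec(separate=True), registry, tmp_path)
        recs, trace = eng.run()
        assert trace.first(2, 1, "running").time < trace.first(1, 3, "succeeded").time
        # index matching: B_x starts only after A_x succeeded
        for x in (1, 2, 3):
            assert (trace.first(2, x, "running").time
                    >= trace.first(1, x, "succeeded").time)

    def test_task_level_input_block_waits_for_all(self, registry, tmp_path):
        eng = engine(pipeline_spec(separate=False), registry, tmp_path)
        recs, trace = eng.run()
        all_a = max(e.time for e in trace.by_transition("succeeded") if e.task_id == 1)
        assert trace.first(2, 1, "running").time >= all_a

    def test_input_instances_carry_upstream_returns(self, registry, tmp_path):
        cfg = VirtualExecutorConfig(
            returns_of={(1, i): {"file": f"/f{i}.bam", "fCount": str(10 * i)}
                        for i in (1, 2, 3)})
        eng = engine(pipeline_spec(separate=True), registry, tmp_path, virtual_config=cfg)
        recs, _ = eng.run()
        assert recs[(2, 2)].instance.var_map == {"file": "/f2.bam", "fCount": "20"}


class TestResourceLimits:
    def cap_spec(self, n=5, cap=2):
        return WorkflowSpec(
            executors=(ExecutorDecl(name="v", exec_type="virtual", max_slots=8,
                                    default=True,
                                    attributes=(("hosts", "1"), ("slotsPerHost", "8"))),),
            blocks=(SequenceBlock("files", 1, n, 1),),
            tasks=(TaskSpec(id=1, name="work", module_ref="echoTask",
                            process_block_ref="files", max_running=cap,
                            parameters=(("value", "{}"),)),),
        )

    def test_per_task_cap_never_exceeded_and_fifth_held(self, registry, tmp_path):
        eng = engine(self.cap_spec(), registry, tmp_path)
        recs, trace = eng.run()
        assert trace.max_concurrent_running(lambda e: e.task_id == 1) == 2
        held = trace.first(1, 5, "held_resource")
        assert held is not None
        # 5th subtask launches only once earlier subtasks finished
        assert trace.first(1, 5, "running").time >= trace.first(1, 1, "succeeded").time

    def test_user_release_of_resource_hold(self, registry, tmp_path):
        eng = engine(self.cap_spec(), registry, tmp_path)
        eng.post_action(1, 5, "release_resource_hold")
        recs, trace = eng.run()
        # cap bypassed for the released subtask: it starts with the first wave
        assert trace.first(1, 5, "running").time == 0.0
        assert trace.max_concurrent_running(lambda e: e.task_id == 1) == 3

    def test_executor_slot_cap(self, registry, tmp_path):
        spec = WorkflowSpec(
            executors=(ExecutorDecl(name="v", exec_type="virtual", max_slots=2,
                                    default=True,
                                    attributes=(("hosts", "1"), ("slotsPerHost", "2"))),),
            blocks=(SequenceBlock("files", 1, 6, 1),),
            tasks=(TaskSpec(id=1, name="work", module_ref="echoTask",
                            process_block_ref="files",
                            parameters=(("value", "{}"),)),),
        )
        eng = engine(spec, registry, tmp_path)
        recs, trace = eng.run()
        assert trace.max_concurrent_running() == 2


class TestCheckpoints:
    def spec(self):
        return chain_spec(2) and WorkflowSpec(tasks=(
            TaskSpec(id=1, name="a", module_ref="noopTask", checkpoint=True),
            TaskSpec(id=2, name="b", module_ref="noopTask",
                     dependencies=(DependencyDecl("1"),)),
        ))

    def test_unreleased_checkpoint_deadlocks_headless_run(self, registry, tmp_path):
        eng = engine(self.spec(), registry, tmp_path)
        with pytest.raises(DeadlockError) as exc:
            eng.run()
        assert exc.value.blocked == {(2, 0)}

    def test_release_lets_dependents_run(self, registry, tmp_path):
        eng = engine(self.spec(), registry, tmp_path)

        def handler(e):
            held = [r for r in e.records.values() if r.state is S.HELD_CHECKPOINT]
            if held:
                e.release_checkpoint("1")
                return True
            return False

        recs, trace = eng.run(action_handler=handler)
        assert recs[(2, 0)].state is S.SUCCEEDED
        assert trace.first(2, 0, "held_checkpoint") is not None

    def test_disable_checkpoints_equals_no_checkpoint_trace(self, registry, tmp_path):
        plain = WorkflowSpec(tasks=(
            TaskSpec(id=1, name="a", module_ref="noopTask"),
            TaskSpec(id=2, name="b", module_ref="noopTask",
                     dependencies=(DependencyDecl("1"),)),
        ))
        eng1 = engine(self.spec(), registry, tmp_path,
                      scope=ScopeFilter(disable_checkpoints=True))
        eng2 = engine(plain, registry, tmp_path / "b")
        _, t1 = eng1.run()
        _, t2 = eng2.run()
        assert t1.to_jsonl() == t2.to_jsonl()

    def test_release_on_checkpoint_less_task_rejected(self, registry, tmp_path):
        eng = engine(chain_spec(2), registry, tmp_path)
        with pytest.raises(SchedulerError, match="no checkpoint"):
            eng.release_checkpoint("1")


class TestResume:
    def test_rerun_with_journal_launches_nothing(self, registry, tmp_path):
        journal = tmp_path / "journal.tsv"
        eng1 = engine(chain_spec(3), registry, tmp_path, journal_path=journal)
        _, t1 = eng1.run()
        assert len(t1.by_transition("running")) == 3
        eng2 = engine(chain_spec(3), registry, tmp_path, journal_path=journal)
        _, t2 = eng2.run()
        assert len(t2.by_transition("running")) == 0
        assert len(t2.by_transition("replayed")) == 3
        assert eng2.all_successful()

    def test_parameter_edit_forces_reexecution(self, registry, tmp_path):
        def spec(value):
            return WorkflowSpec(tasks=(
                TaskSpec(id=1, name="e", module_ref="echoTask",
                         parameters=(("value", value),)),))
        journal = tmp_path / "journal.tsv"
        engine(spec("one"), registry, tmp_path, journal_path=journal).run()
        eng = engine(spec("two"), registry, tmp_path, journal_path=journal)
        _, trace = eng.run()
        assert len(trace.by_transition("running")) == 1  # argv hash changed

    def test_replayed_returns_feed_input_blocks(self, registry, tmp_path):
        journal = tmp_path / "journal.tsv"
        cfg = VirtualExecutorConfig(
            returns_of={(1, i): {"file": f"/f{i}", "fCount": str(i)} for i in (1, 2, 3)})
        engine(pipeline_spec(), registry, tmp_path, journal_path=journal,
               virtual_config=cfg).run()
        eng = engine(pipeline_spec(), registry, tmp_path, journal_path=journal,
                     virtual_config=cfg)
        recs, trace = eng.run()
        assert len(trace.by_transition("running")) == 0
        assert recs[(2, 3)].instance.var_map == {"file": "/f3", "fCount": "3"}


class TestDeterminism:
    def test_identical_runs_identical_traces(self, registry, tmp_path):
        def one(sub):
            eng = engine(barrier_spec(), registry, tmp_path / sub)
            _, trace = eng.run()
            return trace.to_jsonl()
        assert one("x") == one("y")

    def test_trace_round_trips_through_jsonl(self, registry, tmp_path):
        eng = engine(barrier_spec(), registry, tmp_path)
        _, trace = eng.run()
        again = ExecutionTrace.from_jsonl(trace.to_jsonl())
        assert again.to_jsonl() == trace.to_jsonl()


class TestFailureHandling:
    def test_failure_blocks_only_dependency_cone(self, registry, tmp_path):
        # diamond: 1 -> (2 fails, 3 ok) -> 4 depends on 2 and 3; 5 independent
        spec = WorkflowSpec(tasks=(
            TaskSpec(id=1, name="a", module_ref="noopTask"),
            TaskSpec(id=2, name="bad", module_ref="noopTask",
                     dependencies=(DependencyDecl("1"),)),
            TaskSpec(id=3, name="ok", module_ref="noopTask",
                     dependencies=(DependencyDecl("1"),)),
            TaskSpec(id=4, name="joint", module_ref="noopTask",
                     dependencies=(DependencyDecl("2"), DependencyDecl("3"))),
            TaskSpec(id=5, name="solo", module_ref="noopTask"),
        ))
        cfg = VirtualExecutorConfig(exit_code_of={(2, 0): 1})
        eng = engine(spec, registry, tmp_path, virtual_config=cfg)
        recs, _ = eng.run()
        assert recs[(2, 0)].state is S.FAILED_AWAITING_USER
        assert recs[(3, 0)].state is S.SUCCEEDED
        assert recs[(5, 0)].state is S.SUCCEEDED
        assert recs[(4, 0)].state is S.PENDING
        # ignore containment: after ignoring, nothing outside the cone changes
        eng.act(2, 0, "ignore")
        recs, _ = eng.run()
        assert recs[(4, 0)].state is S.PENDING
        assert recs[(3, 0)].state is S.SUCCEEDED and recs[(5, 0)].state is S.SUCCEEDED
        assert not eng.all_successful()

    def test_failed_subtask_carries_message(self, registry, tmp_path):
        cfg = VirtualExecutorConfig(exit_code_of={(1, 0): 9})
        eng = engine(chain_spec(1), registry, tmp_path, virtual_config=cfg)
        recs, _ = eng.run()
        assert any("9" in m for m in recs[(1, 0)].messages)

    def test_restart_after_fix_succeeds(self, registry, tmp_path):
        cfg = VirtualExecutorConfig(exit_code_of={(1, 0): 1})
        eng = engine(chain_spec(2), registry, tmp_path, virtual_config=cfg)
        eng.run()
        # the underlying problem is fixed, then the subtask is restarted
        for ex in eng.executors.values():
            ex.config.exit_code_of.clear()
        eng.act(1, 0, "restart")
        recs, _ = eng.run()
        assert recs[(1, 0)].state is S.SUCCEEDED and recs[(1, 0)].attempt == 2
        assert recs[(2, 0)].state is S.SUCCEEDED

    def test_modify_restart_rerenders_argv(self, registry, tmp_path):
        spec = WorkflowSpec(tasks=(
            TaskSpec(id=1, name="e", module_ref="echoTask",
                     parameters=(("value", "bad"),)),))
        cfg = VirtualExecutorConfig(exit_code_of={(1, 0): 1})
        eng = engine(spec, registry, tmp_path, virtual_config=cfg)
        eng.run()
        assert eng.records[(1, 0)].resolved_argv == ("echo", "--value", "bad")
        for ex in eng.executors.values():
            ex.config.exit_code_of.clear()
        eng.act(1, 0, "modify_restart", params={"value": "good"})
        recs, _ = eng.run()
        assert recs[(1, 0)].resolved_argv == ("echo", "--value", "good")
        assert recs[(1, 0)].state is S.SUCCEEDED

    def test_act_is_idempotent_on_repeat_delivery(self, registry, tmp_path):
        cfg = VirtualExecutorConfig(exit_code_of={(1, 0): 1})
        eng = engine(chain_spec(1), registry, tmp_path, virtual_config=cfg)
        eng.run()
        assert eng.act(1, 0, "ignore") is True
        assert eng.act(1, 0, "ignore") is False

    def test_unknown_subtask_action_rejected(self, registry, tmp_path):
        eng = engine(chain_spec(1), registry, tmp_path)
        with pytest.raises(SchedulerError, match="unknown subtask"):
            eng.act(9, 9, "ignore")


class TestAffinityScheduling:
    def test_slave_mode_pins_chains_to_hosts(self, registry, tmp_path):
        spec = WorkflowSpec(
            executors=(ExecutorDecl(name="v", exec_type="virtual", max_slots=2,
                                    default=True,
                                    attributes=(("hosts", "2"), ("slotsPerHost", "1"),
                                                ("slave", "true"))),),
            blocks=(SequenceBlock("pair", 1, 2, 1),),
            tasks=(
                TaskSpec(id=1, name="A", module_ref="echoTask", process_block_ref="pair",
                         parameters=(("value", "{}"),)),
                TaskSpec(id=2, name="B", module_ref="echoTask", process_block_ref="pair",
                         dependencies=(DependencyDecl("1", separate=True),),
                         parameters=(("value", "{}"),)),
            ),
        )
        eng = engine(spec, registry, tmp_path)
        recs, trace = eng.run()
        hosts = {(e.task_id, e.subtask_index): e.host for e in trace.by_transition("running")}
        assert hosts[(1, 1)] == hosts[(2, 1)]
        assert hosts[(1, 2)] == hosts[(2, 2)]
        assert hosts[(1, 1)] != hosts[(1, 2)]  # chains spread over both hosts


class TestEmptyAndDegenerate:
    def test_empty_workflow(self, registry, tmp_path):
        eng = engine(WorkflowSpec(), registry, tmp_path)
        recs, trace = eng.run()
        assert recs == {} and len(trace) == 0 and eng.all_successful()

    def test_zero_instance_block_is_vacuous_success(self, registry, tmp_path):
        (tmp_path / "empty").mkdir()
        from shepherd.blocks import FolderBlock
        spec = WorkflowSpec(
            blocks=(FolderBlock("none", str(tmp_path / "empty"), "*.log"),),
            tasks=(TaskSpec(id=1, name="a", module_ref="echoTask",
                            process_block_ref="none",
                            parameters=(("value", "{}"),)),),
        )
        eng = engine(spec, registry, tmp_path)
        recs, _ = eng.run()
        assert eng.all_successful()
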