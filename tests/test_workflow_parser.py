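"""Workflow XML parsing, constant resolution, static validation."""

from dataclasses import replace
from textwrap import dedent

import pytest

from shepherd.blocks import FolderBlock, InputBlock, SequenceBlock, TableBlock
from shepherd.exceptions import WorkflowError
from shepherd.workflow import (
    parse_workflow,
    resolve_constants,
    serialize_workflow,
    validate_workflow,
)

SLEEP_WORKFLOW = """\
<watchdog>
  <settings>
    <constants>
      <const name="WAIT_TIME" value="30"/>
    </constants>
  </settings>
  <tasks mail="user@example.org">
    <sleepTask id="1" name="sleep">
      <parameter>
        <wait>${WAIT_TIME}</wait>
      </parameter>
    </sleepTask>
  </tasks>
</watchdog>
"""


def write(tmp_path, text, name="wf.xml"):
    p = tmp_path / name
    p.write_text(dedent(text))
    return p


class TestParse:
    def test_sleep_workflow(self, tmp_path, registry):
        spec = parse_workflow(write(tmp_path, SLEEP_WORKFLOW), registry)
        assert spec.const_map == {"WAIT_TIME": "30"}
        (task,) = spec.tasks
        assert (task.id, task.name, task.module_ref) == (1, "sleep", "sleepTask")
        # constants are untouched at parse time
        assert task.param_map == {"wait": "${WAIT_TIME}"}
        assert spec.task_by_ref("1") is task and spec.task_by_ref("sleep") is task

    def test_settings_blocks_and_executors(self, tmp_path, registry):
        spec = parse_workflow(write(tmp_path, """\
            <watchdog>
              <settings>
                <executors>
                  <executor name="local" type="local" maxSlots="2" default="true"/>
                  <executor name="goliath" type="ssh" maxSlots="4" host="goliath"/>
                  <executor name="grid" type="drmaa" maxSlots="16" queue="short"/>
                </executors>
                <processBlock>
                  <processSequence name="num" start="1" end="9" step="4"/>
                  <processFolder name="logs" folder="/tmp" pattern="*.log"/>
                  <processTable name="tab" table="samples.tsv"/>
                  <processInput name="inp" compareByIndex="true"/>
                </processBlock>
                <moduleFolders><folder path="modules"/></moduleFolders>
              </settings>
              <tasks>
                <noopTask id="1" name="a" executor="grid"/>
              </tasks>
            </watchdog>"""), registry)
        assert [e.name for e in spec.executors] == ["local", "goliath", "grid"]
        assert spec.default_executor.name == "local"
        assert spec.executor_by_name("grid").attr_map == {"queue": "short"}
        assert [type(b) for b in spec.blocks] == [
            SequenceBlock, FolderBlock, TableBlock, InputBlock]
        assert spec.blocks[3].compare_by_index is True
        assert spec.module_folders == ("modules",)

    def test_dependency_cycle_rejected(self, tmp_path, registry):
        wf = """\
            <watchdog><tasks>
              <noopTask id="1" name="a">
                <dependencies><depends>2</depends></dependencies>
              </noopTask>
              <noopTask id="2" name="b">
                <dependencies><depends>1</depends></dependencies>
              </noopTask>
            </tasks></watchdog>"""
        with pytest.raises(WorkflowError, match="cycle"):
            parse_workflow(write(tmp_path, wf), registry)

    @pytest.mark.parametrize(
        "snippet, match",
        [
            ('<noopTask id="1" name="a" executor="goliath2"/>', "unresolved executor"),
            ('<noopTask id="1" name="a" processBlock="nope"/>', "unresolved process block"),
            ('<noopTask id="1" name="a"/><noopTask id="1" name="b"/>', "duplicate task id"),
            ('<noopTask id="1" name="a"/><noopTask id="2" name="a"/>', "duplicate task name"),
            ('<noopTask id="1" name="a"><dependencies><depends>9</depends>'
             "</dependencies></noopTask>", "no task with id or name"),
            ('<ghostTask id="1" name="a"/>', "unknown module"),
        ],
    )
    def test_unresolved_references(self, tmp_path, registry, snippet, match):
        wf = f"<watchdog><tasks>{snippet}</tasks></watchdog>"
        with pytest.raises(WorkflowError, match=match):
            parse_workflow(write(tmp_path, wf), registry)

    def test_xml_syntax_error(self, tmp_path, registry):
        with pytest.raises(WorkflowError, match="XML syntax error"):
            parse_workflow(write(tmp_path, "<watchdog><tasks>"), registry)

    def test_parse_serialize_parse_fixed_point(self, tmp_path, registry):
        wf = """\
            <watchdog>
              <settings>
                <constants><const name="N" value="3"/></constants>
                <executors><executor name="v" type="virtual" maxSlots="4"
                           hosts="2" slotsPerHost="2"/></executors>
                <processBlock><processSequence name="num" start="1" end="3"/></processBlock>
              </settings>
              <tasks>
                <echoTask id="1" name="a" processBlock="num" maxRunning="2" checkpoint="true">
                  <parameter><value>{}</value></parameter>
                  <streams><stdout path="o.txt"/><stderr path="e.txt"/></streams>
                  <environment><var name="LC_ALL" value="C"/></environment>
                  <actions><action phase="before" type="create" src="out/"/></actions>
                  <checkers><checker name="stderr_pattern" kind="error"
                            args="string:Exception,integer:0"/></checkers>
                </echoTask>
                <noopTask id="2" name="b">
                  <dependencies><depends separate="true">a</depends></dependencies>
                </noopTask>
              </tasks>
            </watchdog>"""
        spec1 = parse_workflow(write(tmp_path, wf), registry)
        round_path = tmp_path / "round.xml"
        round_path.write_bytes(serialize_workflow(spec1))
        spec2 = parse_workflow(round_path, registry)
        assert replace(spec2, base_dir=spec1.base_dir) == spec1


class TestConstants:
    def test_fig_constant_resolves_into_parameter(self, tmp_path, registry):
        spec = parse_workflow(write(tmp_path, SLEEP_WORKFLOW), registry)
        resolved = resolve_constants(spec)
        assert resolved.tasks[0].param_map == {"wait": "30"}

    def test_plain_text_unchanged_and_idempotent(self, tmp_path, registry):
        spec = parse_workflow(write(tmp_path, SLEEP_WORKFLOW), registry)
        once = resolve_constants(spec)
        assert resolve_constants(once) == once

    def test_two_level_chain(self, tmp_path, registry):
        wf = """\
            <watchdog>
              <settings><constants>
                <const name="A" value="${B}"/><const name="B" value="x"/>
              </constants></settings>
              <tasks><echoTask id="1" name="a">
                <parameter><value>${A}</value></parameter>
              </echoTask></tasks>
            </watchdog>"""
        spec = resolve_constants(parse_workflow(write(tmp_path, wf), registry))
        assert spec.tasks[0].param_map == {"value": "x"}

    def test_undefined_constant(self, tmp_path, registry):
        wf = """\
            <watchdog><tasks><echoTask id="1" name="a">
              <parameter><value>${GHOST}</value></parameter>
            </echoTask></tasks></watchdog>"""
        with pytest.raises(WorkflowError, match="undefined constant"):
            resolve_constants(parse_workflow(write(tmp_path, wf), registry))

    def test_self_referential_chain_bounded(self, tmp_path, registry):
        wf = """\
            <watchdog>
              <settings><constants><const name="A" value="${A}"/></constants></settings>
              <tasks><echoTask id="1" name="a">
                <parameter><value>${A}</value></parameter>
              </echoTask></tasks>
            </watchdog>"""
        with pytest.raises(WorkflowError, match="depth 10"):
            resolve_constants(parse_workflow(write(tmp_path, wf), registry))

    def test_instance_placeholders_untouched(self, tmp_path, registry):
        wf = """\
            <watchdog>
              <settings>
                <constants><const name="DIR" value="/out"/></constants>
                <processBlock><processSequence name="n" start="1" end="2"/></processBlock>
              </settings>
              <tasks><echoTask id="1" name="a" processBlock="n">
                <parameter><value>${DIR}/{}-[1]</value></parameter>
              </echoTask></tasks>
            </watchdog>"""
        spec = resolve_constants(parse_workflow(write(tmp_path, wf), registry))
        assert spec.tasks[0].param_map == {"value": "/out/{}-[1]"}


class TestValidate:
    def test_clean_workflow_has_no_diagnostics(self, tmp_path, registry):
        spec = parse_workflow(write(tmp_path, SLEEP_WORKFLOW), registry)
        assert validate_workflow(resolve_constants(spec), registry) == []

    def test_type_error_diagnosed(self, tmp_path, registry):
        wf = SLEEP_WORKFLOW.replace("${WAIT_TIME}", "abc")
        spec = parse_workflow(write(tmp_path, wf), registry)
        diags = validate_workflow(resolve_constants(spec), registry)
        assert len(diags) == 1 and diags[0].task_id == 1
        assert "not an integer" in diags[0].message

    def test_placeholder_without_block_diagnosed(self, tmp_path, registry):
        wf = """\
            <watchdog><tasks><echoTask id="1" name="a">
              <parameter><value>{}</value></parameter>
            </echoTask></tasks></watchdog>"""
        diags = validate_workflow(parse_workflow(write(tmp_path, wf), registry), registry)
        assert len(diags) == 1 and "placeholder" in diags[0].message

    def test_missing_required_parameter_diagnosed(self, tmp_path, registry):
        wf = '<watchdog><tasks><sleepTask id="1" name="s"/></tasks></watchdog>'
        diags = validate_workflow(parse_workflow(write(tmp_path, wf), registry), registry)
        assert any("required parameter 'wait'" in d.message for d in diags)

    def test_every_diagnostic_names_an_existing_task(self, tmp_path, registry):
        wf = """\
            <watchdog><tasks>
              <sleepTask id="1" name="s"><parameter><wait>abc</wait></parameter></sleepTask>
              <echoTask id="2" name="e"><parameter><value>[1]</value></parameter></echoTask>
            </tasks></watchdog>"""
        spec = parse_workflow(write(tmp_path, wf), registry)
        task_ids = {t.id for t in spec.tasks}
        diags = validate_workflow(spec, registry)
        assert diags and all(d.task_id in task_ids for d in diags)
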