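import copy

import pytest
from lxml import etree

from contourgraph import fixtures
from contourgraph.commands import (
    CommandError,
    Session,
    parse_script,
    run_command,
    run_script,
    select_nodes,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


@pytest.fixture()
def karate_session(quiet_warnings):
    """Session with the bundled karate-like fixture loaded and grouped."""
    data = fixtures.bundled_dir()
    session = Session(seed=1)
    for namespace, command, args in [
        ("network", "import", {"path": "edges_karate_like.gml"}),
        (
            "table",
            "import",
            {
                "path": "nodes_karate_like.txt",
                "firstRowAsColumnNames": "true",
                "keyColumnIndex": "1",
                "dataTypeList": "s,sl",
            },
        ),
        ("network", "select", {"nodeList": "all"}),
        ("examine", "generate groups", {"selectedGroupColumns": "Community"}),
    ]:
        session, status = run_command(session, namespace, command, args, base_dir=data)
        assert status.ok, status.error
    return session


class TestRunCommand:
    def test_select_six_groups(self, karate_session):
        session, status = run_command(
            karate_session,
            "examine",
            "select groups",
            {"selectedGroups": "A,B,C,D,E,F"},
        )
        assert status.ok
        assert session.sets.selection == ["A", "B", "C", "D", "E", "F"]

    def test_selected_group_singular_spelling_accepted(self, karate_session):
        session, status = run_command(
            karate_session, "examine", "select groups", {"selectedGroup": "A,B"}
        )
        assert status.ok
        assert session.sets.selection == ["A", "B"]

    def test_export_writes_svg(self, karate_session, tmp_path):
        session, _ = run_command(
            karate_session, "examine", "select groups", {"selectedGroups": "A,B,C"}
        )
        session, status = run_command(
            session, "examine", "export", {"path": "out.svg"}, base_dir=tmp_path
        )
        assert status.ok
        tree = etree.parse(str(tmp_path / "out.svg"))
        assert len(tree.findall(f".//{SVG_NS}path")) == 3

    def test_unknown_command_leaves_session_untouched(self, karate_session):
        before = copy.deepcopy(karate_session)
        session, status = run_command(karate_session, "examine", "frobnicate", {})
        assert not status.ok
        assert "unknown command" in status.error
        assert session is karate_session
        assert session == before

    def test_unknown_argument_rejected(self, karate_session):
        _, status = run_command(
            karate_session, "examine", "select groups", {"bogusArg": "x"}
        )
        assert not status.ok and "bogusArg" in status.error

    def test_atomicity_under_injected_failure(self, karate_session, tmp_path):
        """A command that fails mid-way (bad table file) must leave the
        session exactly equal to its pre-command state."""
        bad = tmp_path / "bad.txt"
        bad.write_text("name\tCommunity\nv01\tA\nv02\n")  # width mismatch at line 3
        before = copy.deepcopy(karate_session)
        session, status = run_command(
            karate_session,
            "table",
            "import",
            {"path": str(bad), "dataTypeList": "s,sl"},
        )
        assert not status.ok and "line 3" in status.error
        assert session == before

    def test_remove_groups_clears_selection(self, karate_session):
        session, _ = run_command(
            karate_session, "examine", "select groups", {"selectedGroups": "A"}
        )
        session, status = run_command(session, "examine", "remove groups", {})
        assert status.ok
        assert session.sets.groups == [] and session.sets.selection == []

    def test_update_settings_warns_on_groupless_column(self, karate_session):
        session, status = run_command(
            karate_session,
            "examine",
            "update settings",
            {"selectedGroupColumns": "Community,Component"},
        )
        assert status.ok
        assert any("Component" in m for m in status.messages)

    def test_interact_is_a_scene_building_noop(self, karate_session, tmp_path):
        session, _ = run_command(
            karate_session, "examine", "select groups", {"selectedGroups": "A,B"}
        )
        before = copy.deepcopy(session)
        session, status = run_command(
            session, "examine", "interact", {"path": "debug.svg"}, base_dir=tmp_path
        )
        assert status.ok
        assert any("not supported" in m for m in status.messages)
        assert (tmp_path / "debug.svg").exists()
        # the layout cache may fill, but nothing user-visible changes
        assert session.sets == before.sets and session.settings == before.settings

    def test_success_flag_mirrors_outcome(self, karate_session):
        _, ok_status = run_command(
            karate_session, "examine", "select groups", {"selectedGroups": "A"}
        )
        _, bad_status = run_command(
            karate_session, "examine", "select groups", {"selectedGroups": "NOPE"}
        )
        assert bool(ok_status) and not bool(bad_status)


class TestSelectNodes:
    def test_all(self, karate_session):
        session, status = run_command(
            karate_session, "network", "select", {"nodeList": "all"}
        )
        assert status.ok
        assert len(session.node_selection) == 34

    def test_column_value_match(self, quiet_warnings):
        data = fixtures.bundled_dir()
        session = Session(seed=1)
        session, _ = run_command(
            session,
            "network",
            "import",
            {
                "path": "edges_module.txt",
                "indexColumnSourceInteraction": "2",
                "indexColumnTargetInteraction": "3",
            },
            base_dir=data,
        )
        session, _ = run_command(
            session,
            "table",
            "import",
            {
                "path": "nodes_module.txt",
                "dataTypeList": "s,s,f,f,f,s,s,s,sl,sl,sl,sl",
            },
            base_dir=data,
        )
        session, status = run_command(
            session, "network", "select", {"nodeList": "Module:small"}
        )
        assert status.ok
        assert len(session.node_selection) == 17
        for node in session.node_selection:
            assert session.table.cell(node, "Module") == "small"

    def test_absent_value_gives_empty_selection(self, karate_session):
        session = copy.deepcopy(karate_session)
        select_nodes(session, "Community:absent")
        assert session.node_selection == ()

    def test_unknown_column_errors(self, karate_session):
        session = copy.deepcopy(karate_session)
        with pytest.raises(CommandError, match="unknown column"):
            select_nodes(session, "Nope:small")


class TestScripts:
    def test_use_case_module_workflow_replays(self, tmp_path, quiet_warnings):
        script = fixtures.bundled_dir() / "usecase1.txt"
        session, statuses = run_script(Session(seed=1), script, out_dir=tmp_path)
        assert all(s.ok for s in statuses), [s.error for s in statuses]
        tree = etree.parse(str(tmp_path / "fig1a.svg"))
        assert len(tree.findall(f".//{SVG_NS}path")) == 5
        assert len(tree.findall(f".//{SVG_NS}rect")) == 17

    def test_use_case_community_workflow_replays(self, tmp_path, quiet_warnings):
        script = fixtures.bundled_dir() / "usecase2.txt"
        session, statuses = run_script(Session(seed=1), script, out_dir=tmp_path)
        assert all(s.ok for s in statuses), [s.error for s in statuses]
        tree = etree.parse(str(tmp_path / "fig1b.svg"))
        assert len(tree.findall(f".//{SVG_NS}path")) == 6
        assert len(tree.findall(f".//{SVG_NS}rect")) == 34

    def test_replay_is_byte_identical(self, tmp_path, quiet_warnings):
        script = fixtures.bundled_dir() / "usecase2.txt"
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_script(Session(seed=1), script, out_dir=out1)
        run_script(Session(seed=1), script, out_dir=out2)
        assert (out1 / "fig1b.svg").read_bytes() == (out2 / "fig1b.svg").read_bytes()

    def test_empty_script_changes_nothing(self, tmp_path):
        script = tmp_path / "empty.txt"
        script.write_text("# nothing here\n\n")
        session = Session(seed=3)
        before = copy.deepcopy(session)
        after, statuses = run_script(session, script)
        assert statuses == [] and after == before

    def test_halt_on_first_error(self, tmp_path, quiet_warnings):
        data = fixtures.bundled_dir()
        script = tmp_path / "failing.txt"
        script.write_text(
            f"network import path={data / 'edges_karate_like.gml'}\n"
            "examine frobnicate x=1\n"
            "network select nodeList=all\n"
        )
        session, statuses = run_script(Session(), script)
        assert len(statuses) == 2  # third command never ran
        assert statuses[0].ok and not statuses[1].ok
        assert session.node_selection == ()

    def test_keep_going_runs_everything(self, tmp_path, quiet_warnings):
        data = fixtures.bundled_dir()
        script = tmp_path / "failing.txt"
        script.write_text(
            f"network import path={data / 'edges_karate_like.gml'}\n"
            "examine frobnicate x=1\n"
            "network select nodeList=all\n"
        )
        session, statuses = run_script(Session(), script, keep_going=True)
        assert [s.ok for s in statuses] == [True, False, True]
        assert len(session.node_selection) == 34

    def test_json_script_dialect(self, tmp_path, quiet_warnings):
        import json

        data = fixtures.bundled_dir()
        script = tmp_path / "script.json"
        script.write_text(
            json.dumps(
                [
                    {
                        "namespace": "network",
                        "command": "import",
                        "args": {"path": str(data / "edges_karate_like.gml")},
                    },
                    {"namespace": "network", "command": "select", "args": {"nodeList": "all"}},
                ]
            )
        )
        session, statuses = run_script(Session(), script)
        assert all(s.ok for s in statuses)
        assert len(session.node_selection) == 34

    def test_quoted_values_with_spaces(self, tmp_path):
        script = tmp_path / "s.txt"
        script.write_text('examine update settings labelColumn="My Column"\n')
        records = parse_script(script)
        assert records == [
            ("examine", "update settings", {"labelColumn": "My Column"})
        ]


class TestCli:
    def test_run_subcommand(self, tmp_path, capsys, quiet_warnings):
        from contourgraph.cli import main

        script = fixtures.bundled_dir() / "usecase2.txt"
        rc = main(["--seed", "1", "run", str(script), "--out", str(tmp_path)])
        assert rc == 0
        assert (tmp_path / "fig1b.svg").exists()

    def test_export_subcommand(self, tmp_path, quiet_warnings):
        from contourgraph.cli import main

        data = fixtures.bundled_dir()
        out = tmp_path / "direct.svg"
        rc = main(
            [
                "--seed",
                "2",
                "export",
                "--network",
                str(data / "edges_karate_like.gml"),
                "--table",
                str(data / "nodes_karate_like.txt"),
                "--types",
                "s,sl",
                "--group-columns",
                "Community",
                "--groups",
                "A,B,C",
                "--out",
                str(out),
            ]
        )
        assert rc == 0
        tree = etree.parse(str(out))
        assert len(tree.findall(f".//{SVG_NS}path")) == 3

    def test_config_file_supplies_defaults(self, tmp_path, quiet_warnings):
        from contourgraph.cli import main

        config = tmp_path / "config.txt"
        config.write_text("seed=1\nradius=10\n")
        script = fixtures.bundled_dir() / "usecase2.txt"
        rc = main(
            ["--config", str(config), "run", str(script), "--out", str(tmp_path)]
        )
        assert rc == 0
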