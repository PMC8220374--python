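"""Config schema, file-format round trips and the command-line surface."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from bobkit import io
from bobkit.cli import main
from bobkit.lip import UNDEFINED
from bobkit.margins import Trajectory
from bobkit.models import ModelKind, dof5_model


class TestModelConfig:
    def test_shipped_lip_fixture_valid(self):
        m = io.load_model_config(io.fixture_path("lip"))
        assert m.kind is ModelKind.LIP
        assert m.fl == pytest.approx(0.23)
        assert m.ybar == pytest.approx(1.12)
        assert m.omega == pytest.approx(np.sqrt(9.81 / 1.12))

    def test_shipped_dof5_fixture_valid(self):
        m = io.load_model_config(io.fixture_path("dof5"))
        assert m.kind is ModelKind.DOF5
        assert m.dof_count == 5

    def test_negative_mass_names_field(self, tmp_path):
        cfg = yaml.safe_load(io.fixture_path("dof4").read_text())
        cfg["segment_masses"][1] = -5.0
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(cfg))
        with pytest.raises(io.SchemaError, match="segment_masses"):
            io.load_model_config(bad)

    def test_missing_field_named(self, tmp_path):
        cfg = yaml.safe_load(io.fixture_path("lip").read_text())
        del cfg["standing_com_height"]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(cfg))
        with pytest.raises(io.SchemaError, match="standing_com_height"):
            io.load_model_config(bad)

    def test_unknown_kind_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("kind: DOF7\n")
        with pytest.raises(io.SchemaError, match="kind"):
            io.load_model_config(bad)

    def test_write_read_round_trip(self, tmp_path, ref_params):
        m = dof5_model(ref_params)
        path = tmp_path / "model.yaml"
        io.save_model_config(m, path)
        m2 = io.load_model_config(path)
        assert io.model_hash(m) == io.model_hash(m2)
        assert np.array_equal(m.params.segment_lengths, m2.params.segment_lengths)
        assert np.array_equal(m.params.joint_torque_limits,
                              m2.params.joint_torque_limits)


class TestTabularRoundTrips:
    def test_trajectory_csv_lossless(self, tmp_path, rng):
        t = np.sort(rng.uniform(0, 2, 40))
        t[0], t[-1] = 0.0, 2.0
        traj = Trajectory(t=t, x=rng.normal(0, 1, 40), y=rng.normal(1, 0.1, 40),
                          xdot=rng.normal(0, 1, 40), ydot=rng.normal(0, 1, 40),
                          stance_intact=rng.uniform(size=40) > 0.3,
                          nondimensional=True)
        path = tmp_path / "traj.csv"
        io.write_trajectory_csv(traj, path)
        back = io.read_trajectory_csv(path)
        assert np.array_equal(back.t, traj.t)       # 17 significant digits
        assert np.array_equal(back.x, traj.x)
        assert np.array_equal(back.xdot, traj.xdot)
        assert np.array_equal(back.stance_intact, traj.stance_intact)
        assert back.nondimensional

    def test_bob_csv_lossless(self, tmp_path, lip_settings):
        from test_geometry import make_bob
        x = np.linspace(-0.1, 1.1, 7)
        bob = make_bob(x, -x - 1 / 3, -x + 2 / 3, domain=(-0.1, 1.1))
        bob.settings = lip_settings
        path = tmp_path / "bob.csv"
        io.write_bob_csv(bob, path)
        back = io.read_bob_csv(path)
        for p0, p1 in zip(bob.points, back.points):
            assert p1.x == p0.x
            assert p1.xdot_min == p0.xdot_min
            assert p1.xdot_max == p0.xdot_max
        assert back.domain == bob.domain
        assert back.settings == bob.settings

    def test_margins_json_undefined_token(self, tmp_path):
        from bobkit.geometry import BoundaryMargins
        m = BoundaryMargins(reachable_post=0.1, reachable_ant=-0.047,
                            viable_post=UNDEFINED, viable_ant=0.2)
        path = tmp_path / "margins.json"
        io.write_margins_json(m, path)
        raw = json.loads(path.read_text())
        assert raw["viable_post"] == "undefined"
        back = io.read_margins_json(path)
        assert back.viable_post is UNDEFINED
        assert back.reachable_ant == m.reachable_ant


class TestCli:
    @pytest.fixture()
    def runner(self):
        return CliRunner()

    def test_lip_pipeline_margins(self, runner, tmp_path):
        """build-bob on the LIP fixture followed by margins reproduces the
        analytic result: zero reachable margins, undefined viable margins."""
        out = tmp_path / "run"
        r = runner.invoke(main, ["build-bob", str(io.fixture_path("lip")),
                                 "--x-min", "0", "--x-max", "0.23",
                                 "--n-positions", "11", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "manifest.json").exists()
        r = runner.invoke(main, ["margins", str(out / "bob.csv"),
                                 "--out", str(tmp_path / "m.json")])
        assert r.exit_code == 0, r.output
        m = json.loads((tmp_path / "m.json").read_text())
        assert m["reachable_post"] == pytest.approx(0.0, abs=1e-9)
        assert m["reachable_ant"] == pytest.approx(0.0, abs=1e-9)
        assert m["viable_post"] == "undefined"
        assert m["viable_ant"] == "undefined"

    def test_emos_row_count(self, runner, tmp_path):
        out = tmp_path / "run"
        runner.invoke(main, ["build-bob", str(io.fixture_path("lip")),
                             "--x-min", "0", "--x-max", "0.23",
                             "--n-positions", "5", "--out", str(out)])
        r = runner.invoke(main, ["simulate", str(io.fixture_path("lip")),
                                 "--x0", "0.10", "--xdot0", "0.3",
                                 "--duration", "1.0",
                                 "--out", str(tmp_path / "traj.csv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["emos", str(tmp_path / "traj.csv"),
                                 str(out / "bob.csv"),
                                 "--out", str(tmp_path / "emos.csv")])
        assert r.exit_code == 0, r.output
        import pandas as pd
        traj = pd.read_csv(tmp_path / "traj.csv")
        series = pd.read_csv(tmp_path / "emos.csv")
        assert len(series) == len(traj)  # one eMOS row per input sample

    def test_classify_subcommand(self, runner, tmp_path):
        out = tmp_path / "run"
        runner.invoke(main, ["build-bob", str(io.fixture_path("lip")),
                             "--x-min", "0", "--x-max", "0.23",
                             "--n-positions", "5", "--out", str(out)])
        r = runner.invoke(main, ["classify", str(out / "bob.csv"),
                                 "--x", "0.5", "--xdot", "0.0"])
        assert r.exit_code == 0
        assert r.output.strip() == "STATIC"

    def test_unsupported_targets_reported_exit_zero(self, runner, tmp_path):
        """An empty partition is reported in the output file, not as a
        nonzero exit (computational infeasibility is a result)."""
        out = tmp_path / "run"
        runner.invoke(main, ["build-bob", str(io.fixture_path("lip")),
                             "--x-min", "0", "--x-max", "0.23",
                             "--n-positions", "5", "--out", str(out)])
        r = runner.invoke(main, ["targets", str(out / "bob.csv"),
                                 "--category", "B",
                                 "--out", str(tmp_path / "t.json")])
        assert r.exit_code == 0
        assert "error" in json.loads((tmp_path / "t.json").read_text())

    def test_rerun_is_byte_identical(self, runner, tmp_path):
        """Re-running a subcommand with identical inputs reproduces the
        numeric output byte for byte."""
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            r = runner.invoke(main, ["build-bob", str(io.fixture_path("lip")),
                                     "--x-min", "0", "--x-max", "0.23",
                                     "--n-positions", "7", "--out", str(out),
                                     "--seed", "3"])
            assert r.exit_code == 0
            outs.append((out / "bob.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_fixtures_subcommand(self, runner, tmp_path):
        r = runner.invoke(main, ["fixtures", "--out", str(tmp_path / "fx")])
        assert r.exit_code == 0
        m = io.load_model_config(tmp_path / "fx" / "dof4.yaml")
        assert m.kind is ModelKind.DOF4

    def test_unknown_subcommand_usage_error(self, runner):
        r = runner.invoke(main, ["frobnicate"])
        assert r.exit_code != 0
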