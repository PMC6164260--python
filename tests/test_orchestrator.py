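"""Full operating cycles, the four-cycle scenario and the maze robot."""

import numpy as np
import pytest

import dnacomputer as dc
from dnacomputer.maze import MazeWorld
from dnacomputer.orchestrator import StageError
from tests.conftest import OPERATING_TABLE

ROOM = """\
####
#.>#
#..#
####
"""

CORRIDOR = """\
#######
##...E#
##.####
##^####
#######
"""

OPEN_WORLD = """\
.....
.....
..^..
.....
.....
"""


class TestScenario:
    def test_reproduces_operating_table(self, table3_scenario):
        """The chained four-cycle run reproduces the published per-cycle
        record: thresholder endpoints to 0.01 nM, active gates to
        max(5%, 0.5 pM), state vectors to 5e-3."""
        assert len(table3_scenario.records) == 4
        for row, rec in zip(OPERATING_TABLE, table3_scenario.records):
            assert rec.ob_final == pytest.approx(row["ob_nM"] * 1e-9)
            np.testing.assert_allclose(
                rec.thresholder_endpoint * 1e9, row["thresh_nM"], atol=0.01
            )
            err = np.abs(rec.active_gates * 1e12 - np.asarray(row["gates_pM"]))
            tol = np.maximum(0.05 * np.asarray(row["gates_pM"]), 0.5)
            assert np.all(err <= tol)
            np.testing.assert_allclose(rec.s_final, row["s_final"], atol=5e-3)
            assert rec.winner.gate == row["winner"]

    def test_cycles_chain_through_flush(self, table3_scenario):
        """Only the FSM state survives the flush: each cycle starts from
        the previous final state."""
        recs = table3_scenario.records
        for prev, nxt in zip(recs, recs[1:]):
            np.testing.assert_allclose(prev.s_final, nxt.s_initial, atol=1e-12)

    def test_desired_state_occupancy_exceeds_99_percent(self, table3_scenario):
        assert table3_scenario.min_desired_occupancy() > 0.99

    def test_block_raster_shape(self, table3_scenario):
        blocks = table3_scenario.state_blocks()
        assert set(blocks.columns) == {"time_s", "cycle", "P_F", "P_L", "P_R"}
        # 4 min sampling over four 10 h cycles
        assert len(blocks) == 4 * 150
        norms = np.linalg.norm(blocks[["P_F", "P_L", "P_R"]].to_numpy(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_history_dependence(self, coarse_config):
        forward = dc.run_table3_scenario(coarse_config, input_sequence=(1, 2))
        reverse = dc.run_table3_scenario(coarse_config, input_sequence=(2, 1))
        assert not np.allclose(
            forward.records[-1].s_final, reverse.records[-1].s_final, atol=1e-3
        )

    def test_deterministic_bitwise(self, coarse_config):
        a = dc.run_cycle(coarse_config, 3, (1.0, 0.0, 0.0))
        b = dc.run_cycle(coarse_config, 3, (1.0, 0.0, 0.0))
        np.testing.assert_array_equal(a.thresholder_endpoint, b.thresholder_endpoint)
        np.testing.assert_array_equal(a.active_gates, b.active_gates)
        np.testing.assert_array_equal(a.s_final, b.s_final)

    def test_self_transition_fixed_point(self, coarse_config):
        """Input 2 maps a forward-dominant machine back to F, so repeated
        cycles leave the state essentially unchanged."""
        s = dc.normalize((1.0, 0.0, 0.0))
        first = dc.run_cycle(coarse_config, 2, s)
        second = dc.run_cycle(coarse_config, 2, first.s_final)
        assert np.argmax(second.s_final) == 0
        np.testing.assert_allclose(second.s_final, first.s_final, atol=5e-3)

    def test_invalid_input_index_rejected(self, coarse_config):
        with pytest.raises(ValueError):
            dc.run_cycle(coarse_config, 5, (1, 0, 0))

    def test_stage_failure_carries_stage_identity(self, coarse_config):
        bad = dc.CycleConfig(
            encoding=dc.InputEncoding(ob_lookup={1: 200e-9, 2: 201e-9,
                                                 3: 202e-9, 4: 203e-9})
        ).coarse(10)
        with pytest.raises(StageError, match="thresholder"):
            dc.run_cycle(bad, 1, (1, 0, 0))


class TestSensorEncoding:
    def make_world(self, text):
        return MazeWorld.from_text(text)

    def test_wall_ahead_wins(self):
        world = self.make_world("###\n#^#\n#.#")
        assert dc.encode_sensors(world, (1, 0, 0)) == 1

    def test_rotating_right_reports_cleared_path(self):
        world = self.make_world("#.#\n#^#\n#.#")
        assert dc.encode_sensors(world, (0.1, 0.0, 1.0)) == 2

    def test_left_opening_reports_lost_wall(self):
        world = self.make_world("...\n.^.\n...")
        assert dc.encode_sensors(world, (1, 0, 0)) == 3

    def test_left_wall_present_reports_following(self):
        world = self.make_world("#..\n#^.\n#..")
        assert dc.encode_sensors(world, (1, 0, 0)) == 4


class TestMaze:
    def test_corridor_with_corner_reaches_exit(self, coarse_config):
        """Following the left wall up the corridor, turning right at the
        corner and continuing to the exit."""
        world = MazeWorld.from_text(CORRIDOR)
        traj = dc.run_maze(coarse_config, world, max_cycles=10)
        assert traj.reached_exit
        inputs = [rec.input_index for rec in traj.scenario.records]
        assert inputs == [4, 4, 1, 2, 4, 4]
        states = ["FLR"[int(np.argmax(r.s_final))] for r in traj.scenario.records]
        assert states == ["F", "F", "R", "F", "F", "F"]

    def test_closed_room_circulates(self, coarse_config):
        """In a closed 2x2 room the robot keeps circulating clockwise,
        revisiting poses periodically, without ever entering a wall."""
        world = MazeWorld.from_text(ROOM)
        traj = dc.run_maze(coarse_config, world, max_cycles=16)
        assert traj.exhausted and not traj.reached_exit
        for r, c, _ in traj.poses:
            assert not world.walls[r, c]
        assert traj.poses[0] == traj.poses[8]  # 8-cycle tour of the room

    def test_open_world_never_errors(self, coarse_config):
        world = MazeWorld.from_text(OPEN_WORLD)
        traj = dc.run_maze(coarse_config, world, max_cycles=6)
        assert len(traj.poses) == 7


class TestFullChemistryMode:
    def test_monotone_chain(self, coarse_config):
        """Longer pulse separations give more output, more populated
        thresholder channels and a non-decreasing winner gate."""
        from dataclasses import replace

        cfg = replace(
            coarse_config, mode="full_chemistry",
            encoding=dc.InputEncoding(
                topen_lookup={1: 60.0, 2: 600.0, 3: 1800.0, 4: 3600.0}
            ),
        )
        records = [dc.run_cycle(cfg, i, (1.0, 0.0, 0.0)) for i in (1, 2, 3, 4)]
        obs = [r.ob_final for r in records]
        assert np.all(np.diff(obs) > 0)
        populated = [np.sum(r.thresholder_endpoint > 0.05e-9) for r in records]
        assert np.all(np.diff(populated) >= 0)
        winners = [r.winner.gate for r in records]
        assert np.all(np.diff(winners) >= 0)

    def test_missing_delay_is_reported_as_stage_failure(self, coarse_config):
        from dataclasses import replace

        cfg = replace(coarse_config, mode="full_chemistry")
        with pytest.raises(StageError, match="catalytic_cycle"):
            dc.run_cycle(cfg, 3, (1, 0, 0))

    def test_calibrated_delays_hit_their_targets(self, coarse_config):
        from dataclasses import replace

        cfg = replace(coarse_config, mode="full_chemistry")
        encoding = dc.calibrate_topen(cfg, inputs=(2,), tol=0.05e-9)
        assert encoding.topen_lookup[2] > encoding.topen_lookup[1]
        cfg = replace(cfg, encoding=encoding)
        rec = dc.run_cycle(cfg, 2, (1.0, 0.0, 0.0))
        assert rec.ob_final == pytest.approx(2.8e-9, abs=0.06e-9)
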