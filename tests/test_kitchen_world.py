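"""Geometric world model: grasping, releasing, planning, safety invariants."""

import numpy as np
import pytest

from myokitchen.control_modes import ControlCommand
from myokitchen.kitchen_world import (
    OBJECT_NAMES,
    ObjectSpec,
    ObjState,
    SceneConfig,
    WorldError,
    apply_command,
    auto_pick,
    auto_place,
    check_trial_success,
    init_world,
    nearest_free_slot,
    nearest_object,
    release,
)

MOVE = lambda axis, sign: ControlCommand("move", axis=axis, sign=sign)
OPEN = ControlCommand("open_gripper")
CLOSE = ControlCommand("close_gripper")


def world():
    return init_world()


def goto(w, x=None, y=None, z=None):
    """Drive the robot to a pose through unit move commands."""
    for axis, i, target in (("x", 0, x), ("y", 1, y), ("z", 2, z)):
        if target is None:
            continue
        n = int(round(abs(target - w.robot_pos[i]) / w.config.motion_step))
        sign = 1 if target > w.robot_pos[i] else -1
        for _ in range(n):
            apply_command(w, MOVE(axis, sign))
    return w


def grasp(w, name):
    obj = w.objects[name]
    goto(w, x=obj.pose[0], z=obj.pose[2], y=obj.pose[1])
    while w.grasped is None and w.aperture > 0:
        apply_command(w, CLOSE)
    assert w.grasped == name
    return w


class TestInitWorld:
    def test_default_layout(self):
        w = world()
        assert set(w.objects) == set(OBJECT_NAMES)
        assert all(o.state is ObjState.ON_TABLE for o in w.objects.values())
        assert all(v is None for v in w.slots.values())
        assert w.aperture == w.config.aperture_max
        np.testing.assert_allclose(w.robot_pos, w.config.home)

    def test_apple_is_farthest_from_home(self):
        w = world()
        home = np.array(w.config.home)
        dists = {n: float(np.linalg.norm(home - o.pose)) for n, o in w.objects.items()}
        assert max(dists, key=dists.get) == "apple"

    def test_overlapping_layout_rejected(self):
        bad = SceneConfig(
            objects=(
                ObjectSpec("bottle", 0.0, 0.0, (0.04, 0.2, 0.04)),
                ObjectSpec("cup", 0.01, 0.0, (0.04, 0.09, 0.04)),
                ObjectSpec("croissant", -0.2, -0.15, (0.04, 0.05, 0.09)),
                ObjectSpec("apple", 0.35, 0.22, (0.045, 0.07, 0.045)),
                ObjectSpec("fizzy_drink", -0.25, 0.18, (0.035, 0.12, 0.035)),
            )
        )
        with pytest.raises(WorldError, match="overlap"):
            init_world(bad)

    def test_out_of_bounds_layout_rejected(self):
        bad = SceneConfig(
            objects=(
                ObjectSpec("bottle", 0.6, 0.0, (0.04, 0.2, 0.04)),
                ObjectSpec("cup", 0.0, 0.05, (0.04, 0.09, 0.04)),
                ObjectSpec("croissant", -0.2, -0.15, (0.04, 0.05, 0.09)),
                ObjectSpec("apple", 0.35, 0.22, (0.045, 0.07, 0.045)),
                ObjectSpec("fizzy_drink", -0.25, 0.18, (0.035, 0.12, 0.035)),
            )
        )
        with pytest.raises(WorldError, match="bounds"):
            init_world(bad)


class TestApplyCommand:
    def test_motion_clamps_at_workspace_edge(self):
        w = world()
        for _ in range(300):
            apply_command(w, MOVE("x", +1))
        assert w.robot_pos[0] == pytest.approx(w.config.workspace_x[1])
        before = w.robot_pos.copy()
        apply_command(w, MOVE("x", +1))
        np.testing.assert_allclose(w.robot_pos, before)

    def test_aperture_clamps_both_ends(self):
        w = world()
        for _ in range(30):
            apply_command(w, CLOSE)
        assert w.aperture == 0.0
        for _ in range(30):
            apply_command(w, OPEN)
        assert w.aperture == w.config.aperture_max

    def test_closing_on_object_grasps_it(self):
        w = grasp(world(), "cup")
        assert w.objects["cup"].state is ObjState.GRASPED

    def test_motion_without_interaction_conserves_object_poses(self):
        w = world()
        poses = {n: o.pose.copy() for n, o in w.objects.items()}
        for cmd in [MOVE("x", +1), MOVE("y", -1), MOVE("z", +1)]:
            apply_command(w, cmd)
        for n, p in poses.items():
            np.testing.assert_allclose(w.objects[n].pose, p)

    def test_grasped_object_moves_rigidly_with_robot(self):
        w = grasp(world(), "cup")
        offset = w.objects["cup"].pose - w.robot_pos
        for cmd in [MOVE("y", +1)] * 10 + [MOVE("x", +1)] * 15:
            apply_command(w, cmd)
        np.testing.assert_allclose(w.objects["cup"].pose - w.robot_pos, offset, atol=1e-12)


class TestRelease:
    def test_release_over_free_slot_lands_in_slot(self):
        w = grasp(world(), "cup")
        sx, sz = w.config.slot_center(5)
        goto(w, y=w.config.transport_height, x=sx, z=sz)
        apply_command(w, OPEN)
        assert w.objects["cup"].state is ObjState.IN_SLOT
        assert w.objects["cup"].slot == 5 and w.slots[5] == "cup"

    def test_release_over_table_lands_on_table(self):
        w = grasp(world(), "cup")
        goto(w, y=0.2, x=0.10, z=0.25)
        apply_command(w, OPEN)
        obj = w.objects["cup"]
        assert obj.state is ObjState.ON_TABLE
        assert obj.pose[1] == pytest.approx(obj.collider[1] / 2)

    def test_release_beyond_table_edge_falls_off(self):
        w = grasp(world(), "cup")
        goto(w, y=0.2, x=w.config.workspace_x[1], z=0.25)  # overhanging the edge
        apply_command(w, OPEN)
        assert w.objects["cup"].state is ObjState.FALLEN_OFF

    def test_release_without_grasp_errors(self):
        with pytest.raises(WorldError):
            release(world())


class TestNearest:
    def test_nearest_matches_brute_force_scan(self):
        w = world()
        dists = {n: float(np.linalg.norm(w.robot_pos - o.pose)) for n, o in w.objects.items()}
        assert nearest_object(w) == min(dists, key=dists.get)

    def test_single_remaining_object(self):
        w = world()
        for n in OBJECT_NAMES:
            if n != "apple":
                w.objects[n].state = ObjState.FALLEN_OFF
        assert nearest_object(w) == "apple"

    def test_no_object_remaining_errors(self):
        w = world()
        for n in OBJECT_NAMES:
            w.objects[n].state = ObjState.FALLEN_OFF
        with pytest.raises(WorldError):
            nearest_object(w)

    def test_equidistant_tie_breaks_by_scene_order(self):
        cfg = SceneConfig(
            home=(0.0, 0.30, 0.0),
            objects=(
                ObjectSpec("bottle", -0.10, 0.0, (0.04, 0.2, 0.04)),   # same distance...
                ObjectSpec("croissant", 0.10, 0.0, (0.04, 0.2, 0.04)),  # ...same collider
                ObjectSpec("cup", 0.0, 0.25, (0.04, 0.09, 0.04)),
                ObjectSpec("apple", 0.40, 0.25, (0.045, 0.07, 0.045)),
                ObjectSpec("fizzy_drink", -0.25, -0.20, (0.035, 0.12, 0.035)),
            ),
        )
        assert nearest_object(init_world(cfg)) == "bottle"

    def test_nearest_free_slot_skips_occupied(self):
        w = world()
        sx, sz = w.config.slot_center(1)
        goto(w, x=sx, z=sz)
        assert nearest_free_slot(w) == 1
        w.slots[1] = "cup"
        assert nearest_free_slot(w) != 1


class TestAutoPlanner:
    def test_auto_pick_grasps_and_lifts(self):
        w = world()
        auto_pick(w, "apple")
        assert w.grasped == "apple"
        assert w.robot_pos[1] == pytest.approx(w.config.transport_height)
        assert w.robot_pos[0] == pytest.approx(0.35, abs=w.config.grasp_xz_tol)

    def test_auto_pick_default_equals_nearest(self):
        a, b = world(), world()
        auto_pick(a, None)
        auto_pick(b, nearest_object(world()))
        assert a.grasped == b.grasped
        np.testing.assert_allclose(a.robot_pos, b.robot_pos)

    def test_auto_pick_of_fallen_object_errors(self):
        w = world()
        w.objects["cup"].state = ObjState.FALLEN_OFF
        with pytest.raises(WorldError):
            auto_pick(w, "cup")

    def test_auto_place_without_grasp_errors(self):
        with pytest.raises(WorldError):
            auto_place(world(), 3)

    def test_auto_place_into_occupied_slot_errors(self):
        w = world()
        auto_pick(w, "cup")
        auto_place(w, 3)
        auto_pick(w, "apple")
        with pytest.raises(WorldError, match="occupied"):
            auto_place(w, 3)

    @pytest.mark.parametrize("name", OBJECT_NAMES)
    def test_pick_place_succeeds_for_every_object_slot_pair(self, name):
        for slot in range(1, 10):
            w = world()
            auto_pick(w, name)
            auto_place(w, slot)
            assert check_trial_success(w, name, slot)
            assert not check_trial_success(w, name, slot % 9 + 1)  # wrong slot

    def test_success_false_for_fallen_object(self):
        w = world()
        w.objects["cup"].state = ObjState.FALLEN_OFF
        assert not check_trial_success(w, "cup", 1)


class TestFuzzInvariants:
    def test_random_command_stream_preserves_safety(self):
        rng = np.random.default_rng(1234)
        w = world()
        cfg = w.config
        commands = [MOVE(a, s) for a in "xyz" for s in (-1, 1)] + [OPEN, CLOSE]
        for i in range(2000):
            apply_command(w, commands[rng.integers(len(commands))])
            if i % 50 == 0:
                assert cfg.workspace_x[0] <= w.robot_pos[0] <= cfg.workspace_x[1]
                assert 0.0 <= w.robot_pos[1] <= cfg.y_max
                assert cfg.workspace_z[0] <= w.robot_pos[2] <= cfg.workspace_z[1]
                assert 0.0 <= w.aperture <= cfg.aperture_max
                assert set(w.objects) == set(OBJECT_NAMES)
                states = [o.state for o in w.objects.values()]
                assert all(s in ObjState for s in states)
                assert states.count(ObjState.GRASPED) <= 1

    def test_no_teleportation_per_step(self):
        rng = np.random.default_rng(99)
        w = world()
        commands = [MOVE(a, s) for a in "xyz" for s in (-1, 1)]
        for _ in range(500):
            before = w.robot_pos.copy()
            apply_command(w, commands[rng.integers(len(commands))])
            assert np.linalg.norm(w.robot_pos - before) <= w.config.motion_step + 1e-12
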