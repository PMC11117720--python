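"""Headless geometric model of the virtual kitchen pick-and-place task.

A 3-DOF Cartesian robot (prismatic x/y/z axes, y vertical) with a parallel
two-finger gripper operates above a table carrying five everyday objects
(bottle, croissant, cup, apple, fizzy drink) and a nine-slot storage box.
The model is quasi-static: no rigid-body dynamics, objects settle
instantaneously onto the support directly beneath them when released.
Objects released with their centre beyond the table footprint fall off and
are unrecoverable for the rest of the trial.

The robot's reachable workspace extends slightly past the table edge in x
and z, which is what makes dropping an object off the table possible.

All geometry lives in :class:`SceneConfig`; the defaults put every
coordinate on a 1 cm grid and place the apple farthest from the robot's
home pose.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .control_modes import ControlCommand

__all__ = [
    "ObjectSpec",
    "SceneConfig",
    "ObjState",
    "SceneObject",
    "WorldState",
    "init_world",
    "apply_command",
    "release",
    "nearest_object",
    "nearest_free_slot",
    "auto_pick",
    "auto_place",
    "check_trial_success",
    "WorldError",
]

OBJECT_NAMES = ("bottle", "croissant", "cup", "apple", "fizzy_drink")


class WorldError(ValueError):
    """Raised for infeasible world operations (bad layout, invalid auto action)."""


@dataclass(frozen=True)
class ObjectSpec:
    """Initial placement and axis-aligned collider of one scene object."""

    name: str
    x: float
    z: float
    collider: tuple[float, float, float]  # (wx, wy, wz) in metres


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry and robot motion parameters (metres, seconds)."""

    table_x: tuple[float, float] = (-0.50, 0.50)
    table_z: tuple[float, float] = (-0.30, 0.30)
    workspace_margin: float = 0.06  # robot may overhang the table edge by this much
    y_max: float = 0.45
    home: tuple[float, float, float] = (-0.40, 0.30, 0.00)
    motion_step: float = 0.01  # metres per move command
    aperture_step: float = 0.005
    aperture_max: float = 0.05
    grasp_xz_tol: float = 0.04  # finger-footprint half-width
    grasp_y_tol: float = 0.06
    transport_height: float = 0.25
    auto_step_dt: float = 0.02  # seconds per primitive during automatic motion
    slot_centers_x: tuple[float, float, float] = (0.25, 0.35, 0.45)
    slot_centers_z: tuple[float, float, float] = (-0.25, -0.15, -0.05)
    slot_pitch: float = 0.10
    objects: tuple[ObjectSpec, ...] = (
        ObjectSpec("bottle", -0.10, 0.20, (0.040, 0.20, 0.040)),
        ObjectSpec("croissant", -0.20, -0.15, (0.040, 0.05, 0.090)),
        ObjectSpec("cup", 0.00, 0.05, (0.040, 0.09, 0.040)),
        ObjectSpec("apple", 0.35, 0.22, (0.045, 0.07, 0.045)),
        ObjectSpec("fizzy_drink", -0.25, 0.18, (0.035, 0.12, 0.035)),
    )

    @property
    def workspace_x(self) -> tuple[float, float]:
        return (self.table_x[0] - self.workspace_margin, self.table_x[1] + self.workspace_margin)

    @property
    def workspace_z(self) -> tuple[float, float]:
        return (self.table_z[0] - self.workspace_margin, self.table_z[1] + self.workspace_margin)

    def slot_center(self, slot: int) -> tuple[float, float]:
        """Centre (x, z) of slot ``slot`` (1..9, row-major over z then x)."""
        if not 1 <= slot <= 9:
            raise WorldError(f"slot must be 1..9, got {slot}")
        i, j = divmod(slot - 1, 3)
        return self.slot_centers_x[j], self.slot_centers_z[i]

    def slot_at(self, x: float, z: float) -> Optional[int]:
        """Slot whose cell contains (x, z), or None."""
        half = self.slot_pitch / 2.0
        for k in range(1, 10):
            sx, sz = self.slot_center(k)
            if abs(x - sx) <= half and abs(z - sz) <= half:
                return k
        return None


class ObjState(str, Enum):
    ON_TABLE = "on_table"
    GRASPED = "grasped"
    IN_SLOT = "in_slot"
    FALLEN_OFF = "fallen_off"


@dataclass
class SceneObject:
    name: str
    pose: np.ndarray  # centre position (x, y, z)
    collider: tuple[float, float, float]
    state: ObjState = ObjState.ON_TABLE
    slot: Optional[int] = None


@dataclass
class WorldState:
    """Full simulation state; mutated in place by the operations below."""

    config: SceneConfig
    robot_pos: np.ndarray
    aperture: float
    grasped: Optional[str]
    grasp_offset: Optional[np.ndarray]
    objects: dict[str, SceneObject]
    slots: dict[int, Optional[str]]
    time: float = 0.0

    def object(self, name: str) -> SceneObject:
        return self.objects[name]

    def copy(self) -> "WorldState":
        return copy.deepcopy(self)

    def snapshot(self) -> dict:
        """JSON-serializable snapshot for logging/replay."""
        return {
            "time_s": self.time,
            "robot_pos": [float(v) for v in self.robot_pos],
            "aperture_m": self.aperture,
            "grasped": self.grasped,
            "objects": {
                o.name: {
                    "pose": [float(v) for v in o.pose],
                    "state": o.state.value,
                    "slot": o.slot,
                }
                for o in self.objects.values()
            },
            "slots": {str(k): v for k, v in self.slots.items()},
        }


def _overlap_xz(a: ObjectSpec, b: ObjectSpec) -> bool:
    return abs(a.x - b.x) < (a.collider[0] + b.collider[0]) / 2 and abs(a.z - b.z) < (
        a.collider[2] + b.collider[2]
    ) / 2


def init_world(layout: SceneConfig | None = None, seed: int | None = None) -> WorldState:
    """Build the initial world: robot home, gripper open, all slots empty.

    The ``seed`` is accepted for interface symmetry with the stochastic
    modules; the default construction is fully deterministic.
    """
    cfg = layout or SceneConfig()
    names = [o.name for o in cfg.objects]
    if sorted(names) != sorted(OBJECT_NAMES):
        raise WorldError(f"layout must place exactly the five objects {OBJECT_NAMES}")
    for spec in cfg.objects:
        if not (
            cfg.table_x[0] + spec.collider[0] / 2 <= spec.x <= cfg.table_x[1] - spec.collider[0] / 2
            and cfg.table_z[0] + spec.collider[2] / 2 <= spec.z <= cfg.table_z[1] - spec.collider[2] / 2
        ):
            raise WorldError(f"object {spec.name} initial pose is outside the table bounds")
    for i, a in enumerate(cfg.objects):
        for b in cfg.objects[i + 1 :]:
            if _overlap_xz(a, b):
                raise WorldError(f"objects {a.name} and {b.name} overlap in the initial layout")
    objects = {
        spec.name: SceneObject(
            spec.name,
            np.array([spec.x, spec.collider[1] / 2.0, spec.z]),
            spec.collider,
        )
        for spec in cfg.objects
    }
    return WorldState(
        config=cfg,
        robot_pos=np.array(cfg.home, dtype=float),
        aperture=cfg.aperture_max,
        grasped=None,
        grasp_offset=None,
        objects=objects,
        slots={k: None for k in range(1, 10)},
    )


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def _clamp_pos(cfg: SceneConfig, pos: np.ndarray) -> np.ndarray:
    pos[0] = min(max(pos[0], cfg.workspace_x[0]), cfg.workspace_x[1])
    pos[1] = min(max(pos[1], 0.0), cfg.y_max)
    pos[2] = min(max(pos[2], cfg.workspace_z[0]), cfg.workspace_z[1])
    return pos


def _try_grasp(w: WorldState) -> None:
    cfg = w.config
    candidates = []
    for o in w.objects.values():
        if o.state is not ObjState.ON_TABLE:
            continue
        dx = abs(w.robot_pos[0] - o.pose[0])
        dz = abs(w.robot_pos[2] - o.pose[2])
        dy = abs(w.robot_pos[1] - o.pose[1])
        if dx <= cfg.grasp_xz_tol and dz <= cfg.grasp_xz_tol and dy <= cfg.grasp_y_tol:
            if w.aperture <= o.collider[0]:
                candidates.append((math.hypot(dx, dz), o.name))
    if candidates:
        candidates.sort()
        name = candidates[0][1]
        obj = w.objects[name]
        obj.state = ObjState.GRASPED
        obj.slot = None
        w.grasped = name
        w.grasp_offset = obj.pose - w.robot_pos


def apply_command(w: WorldState, c: ControlCommand, dt: float = 0.1) -> WorldState:
    """Apply one robot command; motion clamps at limits, never raises.

    Closing the gripper onto an object whose collider sits between the
    fingers grasps it; opening while grasping releases it (see
    :func:`release`).  Non-actuation verbs only advance time.
    """
    cfg = w.config
    if c.verb == "move":
        step = np.zeros(3)
        step[_AXIS_INDEX[c.axis]] = c.sign * cfg.motion_step
        w.robot_pos = _clamp_pos(cfg, w.robot_pos + step)
        if w.grasped is not None:
            w.objects[w.grasped].pose = w.robot_pos + w.grasp_offset
    elif c.verb == "close_gripper":
        w.aperture = max(0.0, w.aperture - cfg.aperture_step)
        if w.grasped is None:
            _try_grasp(w)
    elif c.verb == "open_gripper":
        w.aperture = min(cfg.aperture_max, w.aperture + cfg.aperture_step)
        if w.grasped is not None:
            release(w)
    w.time += dt
    return w


def release(w: WorldState) -> WorldState:
    """Detach the grasped object and settle it onto the support below.

    Over a free box slot it lands in that slot; over the table (including
    an occupied slot, where it comes to rest on top of the box) it lands on
    the table surface; with its centre beyond the table footprint it falls
    off and becomes unrecoverable.
    """
    if w.grasped is None:
        raise WorldError("release called with no grasped object")
    cfg = w.config
    obj = w.objects[w.grasped]
    x, _, z = obj.pose
    w.grasped = None
    w.grasp_offset = None
    slot = cfg.slot_at(x, z)
    if slot is not None and w.slots[slot] is None:
        sx, sz = cfg.slot_center(slot)
        obj.pose = np.array([sx, obj.collider[1] / 2.0, sz])
        obj.state = ObjState.IN_SLOT
        obj.slot = slot
        w.slots[slot] = obj.name
    elif cfg.table_x[0] <= x <= cfg.table_x[1] and cfg.table_z[0] <= z <= cfg.table_z[1]:
        obj.pose = np.array([x, obj.collider[1] / 2.0, z])
        obj.state = ObjState.ON_TABLE
        obj.slot = None
    else:
        obj.pose = np.array([x, -0.5, z])
        obj.state = ObjState.FALLEN_OFF
        obj.slot = None
    return w


def nearest_object(w: WorldState) -> str:
    """Name of the graspable (on-table) object closest to the end effector.

    Ties break by scene order.
    """
    best = None
    for i, spec in enumerate(w.config.objects):
        o = w.objects[spec.name]
        if o.state is not ObjState.ON_TABLE:
            continue
        d = float(np.linalg.norm(w.robot_pos - o.pose))
        if best is None or d < best[0] - 1e-12:
            best = (d, i, o.name)
    if best is None:
        raise WorldError("no graspable object remains on the table")
    return best[2]


def nearest_free_slot(w: WorldState) -> int:
    """Unoccupied slot whose centre is closest to the end effector (x, z)."""
    free = [k for k, v in w.slots.items() if v is None]
    if not free:
        raise WorldError("no free slot remains")
    def dist(k: int) -> float:
        sx, sz = w.config.slot_center(k)
        return math.hypot(w.robot_pos[0] - sx, w.robot_pos[2] - sz)
    return min(free, key=lambda k: (dist(k), k))


def _auto_move_to(w: WorldState, axis: str, target: float) -> None:
    cfg = w.config
    i = _AXIS_INDEX[axis]
    n = int(round(abs(target - w.robot_pos[i]) / cfg.motion_step))
    sign = 1 if target > w.robot_pos[i] else -1
    for _ in range(n):
        apply_command(w, ControlCommand("move", axis=axis, sign=sign), cfg.auto_step_dt)


def auto_pick(w: WorldState, target: str | None = None) -> WorldState:
    """Automatic pick: approach, descend, grasp, lift to transport height.

    ``target=None`` picks the object nearest the end effector.  The whole
    sequence is executed through the same motion primitives as manual
    control, so workspace clamping and grasp rules apply identically.
    """
    if target is None:
        target = nearest_object(w)
    if target not in w.objects:
        raise WorldError(f"unknown object {target!r}")
    obj = w.objects[target]
    if obj.state is not ObjState.ON_TABLE:
        raise WorldError(f"object {target} is not graspable (state: {obj.state.value})")
    if w.grasped is not None:
        raise WorldError(f"cannot pick {target}: already grasping {w.grasped}")
    cfg = w.config
    while w.aperture < cfg.aperture_max:
        apply_command(w, ControlCommand("open_gripper"), cfg.auto_step_dt)
    _auto_move_to(w, "y", cfg.transport_height)
    _auto_move_to(w, "x", obj.pose[0])
    _auto_move_to(w, "z", obj.pose[2])
    _auto_move_to(w, "y", obj.pose[1])
    guard = 0
    while w.grasped != target and w.aperture > 0.0:
        apply_command(w, ControlCommand("close_gripper"), cfg.auto_step_dt)
        guard += 1
        if guard > 100:  # pragma: no cover - defensive
            break
    if w.grasped != target:
        raise WorldError(f"automatic grasp of {target} failed")
    _auto_move_to(w, "y", cfg.transport_height)
    return w


def auto_place(w: WorldState, slot: int) -> WorldState:
    """Automatic place of the grasped object into box slot ``slot`` (1..9)."""
    if w.grasped is None:
        raise WorldError("auto_place called with no grasped object")
    if not 1 <= slot <= 9:
        raise WorldError(f"slot must be 1..9, got {slot}")
    if w.slots[slot] is not None:
        raise WorldError(f"slot {slot} is already occupied by {w.slots[slot]}")
    cfg = w.config
    sx, sz = cfg.slot_center(slot)
    _auto_move_to(w, "y", cfg.transport_height)
    _auto_move_to(w, "x", sx)
    _auto_move_to(w, "z", sz)
    while w.grasped is not None:
        apply_command(w, ControlCommand("open_gripper"), cfg.auto_step_dt)
    return w


def check_trial_success(w: WorldState, object_name: str, slot: int) -> bool:
    """True iff the named object sits in the named box slot."""
    obj = w.objects.get(object_name)
    return obj is not None and obj.state is ObjState.IN_SLOT and obj.slot == slot
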