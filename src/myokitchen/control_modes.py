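"""Finite-state-machine control modes mapping movements to robot commands.

Three autonomy levels share the same detected-movement vocabulary but spend
it differently:

* **Mode 1** — free motion on all three axes plus manual gripper control.
  Four states (X axis, Y axis, Z axis, gripper); co-contraction cycles
  between them.  In an axis state flexion moves one step along the negative
  axis and extension along the positive axis, every window the movement is
  held (level-triggered).  In the gripper state flexion closes and
  extension opens the fingers.
* **Mode 2** — free motion on x and z; grasping is automatic.  Three states
  (X, Z, pick/place); in the pick/place state a flexion event triggers an
  automatic pick of the nearest object and an extension event an automatic
  place at the nearest free slot.
* **Mode 3** — fully automatic motion.  The user navigates menus (objects,
  then destination slots) with flexion/extension events and selects by
  resting on an option for a dwell period; co-contraction has no function
  in this mode.  The object→destination phase change happens only when the
  robot reports that the automatic pick or place has finished.

Motion gestures act on every window they are held; switching and auto
triggers act once per movement event (on its first window, ``edge=True``).
This keeps a held co-contraction from spinning through states while letting
a held flexion produce sustained motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .onoff_classifier import Movement

__all__ = [
    "Mode1State",
    "Mode2State",
    "Mode3Phase",
    "ModeState",
    "ControlCommand",
    "FsmConfig",
    "initial_state",
    "mode1_step",
    "mode2_step",
    "mode3_step",
    "notify_auto_done",
    "NONE_COMMAND",
]


class Mode1State(str, Enum):
    AXIS_X = "axis_x"
    AXIS_Y = "axis_y"
    AXIS_Z = "axis_z"
    GRIPPER = "gripper"


class Mode2State(str, Enum):
    AXIS_X = "axis_x"
    AXIS_Z = "axis_z"
    PICKPLACE = "pickplace"


class Mode3Phase(str, Enum):
    SELECT_OBJECT = "select_object"
    SELECT_DESTINATION = "select_destination"


_AXIS_OF = {
    Mode1State.AXIS_X: "x",
    Mode1State.AXIS_Y: "y",
    Mode1State.AXIS_Z: "z",
    Mode2State.AXIS_X: "x",
    Mode2State.AXIS_Z: "z",
}


@dataclass(frozen=True)
class ControlCommand:
    """One robot command emitted by a mode FSM for one decision window."""

    verb: str  # move | open_gripper | close_gripper | auto_pick | auto_place
    #        | cursor_move | select | none
    axis: Optional[str] = None  # {x, y, z}, present iff verb == "move"
    sign: Optional[int] = None  # ±1 for move / cursor_move
    cursor: Optional[int] = None  # menu index for select

    def __post_init__(self) -> None:
        if (self.verb == "move") != (self.axis is not None):
            raise ValueError("axis must be present exactly when verb is 'move'")
        if (self.verb in ("move", "cursor_move")) != (self.sign is not None):
            raise ValueError("sign must be present exactly for move/cursor_move")


NONE_COMMAND = ControlCommand("none")


@dataclass(frozen=True)
class FsmConfig:
    """Tunable FSM parameters (state cycle orders, auto mapping, dwell)."""

    mode1_cycle: tuple[Mode1State, ...] = (
        Mode1State.AXIS_X,
        Mode1State.AXIS_Y,
        Mode1State.AXIS_Z,
        Mode1State.GRIPPER,
    )
    mode2_cycle: tuple[Mode2State, ...] = (
        Mode2State.AXIS_X,
        Mode2State.AXIS_Z,
        Mode2State.PICKPLACE,
    )
    #: which gesture triggers the automatic pick in mode 2 (the other
    #: gesture triggers the place); flexion-to-pick parallels
    #: flexion-to-close in mode 1.
    pick_gesture: Movement = Movement.FLEXION
    #: consecutive rest windows required to select a highlighted option in
    #: mode 3 (10 windows at the 10 Hz decision rate = 1.0 s).
    dwell_windows: int = 10


@dataclass(frozen=True)
class ModeState:
    """Current FSM state; immutable, stepped functionally."""

    mode: int
    state: Mode1State | Mode2State | Mode3Phase
    cursor: int = 0
    rest_run: int = 0
    pending_auto: Optional[str] = None  # "pick" | "place" awaiting completion
    n_objects: int = 5
    n_slots: int = 9

    @property
    def menu_size(self) -> int:
        if self.state is Mode3Phase.SELECT_OBJECT:
            return self.n_objects
        return self.n_slots


def initial_state(mode: int, config: FsmConfig | None = None, n_objects: int = 5, n_slots: int = 9) -> ModeState:
    config = config or FsmConfig()
    if mode == 1:
        return ModeState(1, config.mode1_cycle[0])
    if mode == 2:
        return ModeState(2, config.mode2_cycle[0])
    if mode == 3:
        return ModeState(3, Mode3Phase.SELECT_OBJECT, n_objects=n_objects, n_slots=n_slots)
    raise ValueError(f"mode must be 1, 2 or 3, got {mode}")


def _cycle(current, order):
    return order[(order.index(current) + 1) % len(order)]


def mode1_step(
    s: ModeState, label: Movement, edge: bool, config: FsmConfig | None = None
) -> tuple[ModeState, ControlCommand]:
    """Advance the mode-1 FSM by one decision window."""
    if s.mode != 1:
        raise ValueError(f"mode1_step applied to mode-{s.mode} state")
    config = config or FsmConfig()
    if label is Movement.COCONTRACTION:
        if edge:
            return replace(s, state=_cycle(s.state, config.mode1_cycle)), NONE_COMMAND
        return s, NONE_COMMAND
    if label is Movement.REST:
        return s, NONE_COMMAND
    if s.state is Mode1State.GRIPPER:
        verb = "close_gripper" if label is Movement.FLEXION else "open_gripper"
        return s, ControlCommand(verb)
    sign = -1 if label is Movement.FLEXION else +1
    return s, ControlCommand("move", axis=_AXIS_OF[s.state], sign=sign)


def mode2_step(
    s: ModeState, label: Movement, edge: bool, config: FsmConfig | None = None
) -> tuple[ModeState, ControlCommand]:
    """Advance the mode-2 FSM by one decision window."""
    if s.mode != 2:
        raise ValueError(f"mode2_step applied to mode-{s.mode} state")
    config = config or FsmConfig()
    if label is Movement.COCONTRACTION:
        if edge:
            return replace(s, state=_cycle(s.state, config.mode2_cycle)), NONE_COMMAND
        return s, NONE_COMMAND
    if label is Movement.REST:
        return s, NONE_COMMAND
    if s.state is Mode2State.PICKPLACE:
        if not edge:
            return s, NONE_COMMAND
        verb = "auto_pick" if label is config.pick_gesture else "auto_place"
        return s, ControlCommand(verb)
    sign = -1 if label is Movement.FLEXION else +1
    return s, ControlCommand("move", axis=_AXIS_OF[s.state], sign=sign)


def mode3_step(
    s: ModeState, label: Movement, edge: bool, dwell_windows: int = 10
) -> tuple[ModeState, ControlCommand]:
    """Advance the mode-3 FSM by one decision window.

    Flexion/extension events move the menu cursor (wrapping at the ends);
    resting for ``dwell_windows`` consecutive windows selects the
    highlighted option, which dispatches the automatic pick or place.
    Co-contraction is ignored entirely.
    """
    if s.mode != 3:
        raise ValueError(f"mode3_step applied to mode-{s.mode} state")
    if label is Movement.COCONTRACTION:
        return replace(s, rest_run=0), NONE_COMMAND
    if label is Movement.REST:
        run = s.rest_run + 1
        if run == dwell_windows and s.pending_auto is None:
            pending = "pick" if s.state is Mode3Phase.SELECT_OBJECT else "place"
            return (
                replace(s, rest_run=run, pending_auto=pending),
                ControlCommand("select", cursor=s.cursor),
            )
        return replace(s, rest_run=run), NONE_COMMAND
    # flexion or extension
    if not edge:
        return replace(s, rest_run=0), NONE_COMMAND
    sign = -1 if label is Movement.FLEXION else +1
    cursor = (s.cursor + sign) % s.menu_size
    return replace(s, cursor=cursor, rest_run=0), ControlCommand("cursor_move", sign=sign)


def notify_auto_done(s: ModeState) -> ModeState:
    """Report completion of an automatic pick/place to the mode-3 FSM.

    Moves the phase forward (object selection → destination selection after
    a pick; back after a place) and resets the cursor.
    """
    if s.mode != 3:
        raise ValueError("notify_auto_done only applies to mode 3")
    if s.pending_auto is None:
        raise ValueError("no automatic action is pending")
    phase = (
        Mode3Phase.SELECT_DESTINATION
        if s.state is Mode3Phase.SELECT_OBJECT
        else Mode3Phase.SELECT_OBJECT
    )
    return replace(s, state=phase, cursor=0, rest_run=0, pending_auto=None)


def cancel_pending_auto(s: ModeState) -> ModeState:
    """Clear a pending automatic action that could not be executed."""
    return replace(s, pending_auto=None, rest_run=0)
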