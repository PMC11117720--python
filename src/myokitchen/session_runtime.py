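"""Closed-loop session runtime: envelope → classifier → FSM → world.

Ties every stage together at the 10 Hz decision rate, reproduces the
evaluation protocol (five objects × three control modes per user), tallies
per-trial movement-event counts, and renders text biofeedback.

The :func:`oracle_user` scripted participant computes, from world geometry
and FSM semantics alone, a gesture sequence that completes a given task.
Feeding its script through the EMG synthesizer and :func:`run_trial`
exercises the whole platform end to end without a human in the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import control_modes as cm
from .config import AppConfig, default_config
from .control_modes import ControlCommand, FsmConfig, ModeState
from .emg_synthesis import EmgTrace, GestureEntry, GestureScript, SynthParams, synthesize_trace
from .kitchen_world import (
    ObjState,
    SceneConfig,
    WorldError,
    WorldState,
    apply_command,
    auto_pick,
    auto_place,
    check_trial_success,
    init_world,
    nearest_free_slot,
)
from .onoff_classifier import (
    Movement,
    MovementEvent,
    Thresholds,
    classify_trace,
    segment_events,
)
from .signal_conditioning import EnvelopeTrace, condition

__all__ = [
    "TrialResult",
    "SessionLog",
    "BiofeedbackStatus",
    "DecisionRecord",
    "run_trial",
    "oracle_user",
    "run_session",
    "default_protocol",
    "biofeedback",
    "render_status",
    "report",
]


@dataclass(frozen=True)
class TrialResult:
    """Outcome and movement-event counts of one pick-and-place trial."""

    user_id: str
    mode: int
    object_name: str
    slot: int
    n_flexion: int
    n_extension: int
    n_cocontraction: int
    duration_s: float
    success: bool
    failure_reason: str = "none"  # none | fallen_object | timeout | aborted

    def __post_init__(self) -> None:
        if self.success and self.failure_reason != "none":
            raise ValueError("successful trials cannot carry a failure reason")


@dataclass
class SessionLog:
    """Ordered trial results for one user plus session-level bookkeeping."""

    user_id: str
    thresholds: Thresholds
    trials: list[TrialResult] = field(default_factory=list)
    total_time_min: float = 0.0
    schema_version: int = 1

    @property
    def success_rate(self) -> float:
        """Percentage of successful trials."""
        if not self.trials:
            return 0.0
        return 100.0 * sum(t.success for t in self.trials) / len(self.trials)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": self.schema_version,
            "user_id": self.user_id,
            "thresholds": {"tvf_uV": self.thresholds.tvf, "tve_uV": self.thresholds.tve},
            "total_time_min": self.total_time_min,
            "success_rate_pct": self.success_rate,
            "trials": [asdict(t) for t in self.trials],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionLog":
        doc = json.loads(Path(path).read_text())
        log = cls(
            user_id=doc["user_id"],
            thresholds=Thresholds(doc["thresholds"]["tvf_uV"], doc["thresholds"]["tve_uV"]),
            total_time_min=doc["total_time_min"],
            schema_version=doc.get("schema_version", 1),
        )
        log.trials = [TrialResult(**t) for t in doc["trials"]]
        return log


@dataclass(frozen=True)
class DecisionRecord:
    """Per-window audit entry of the classifier/FSM pipeline."""

    time_s: float
    label: Movement
    edge: bool
    state_before: str
    command: str
    state_after: str


@dataclass(frozen=True)
class BiofeedbackStatus:
    """Text-form biofeedback: FSM state, envelope amplitudes, detection bands.

    A channel band is ``green`` when its amplitude strictly exceeds the
    channel threshold (movement detected) and ``yellow`` otherwise.  The
    trajectory trace is exposed in mode 1 only, where the user steers all
    three axes manually.
    """

    state_name: str
    avf: float
    ave: float
    flexor_band: str
    extensor_band: str
    trajectory: Optional[tuple[tuple[float, float, float], ...]] = None


def biofeedback(
    state: ModeState,
    avf: float,
    ave: float,
    thr: Thresholds,
    trajectory: Sequence[tuple[float, float, float]] | None = None,
) -> BiofeedbackStatus:
    return BiofeedbackStatus(
        state_name=str(state.state.value),
        avf=float(avf),
        ave=float(ave),
        flexor_band="green" if avf > thr.tvf else "yellow",
        extensor_band="green" if ave > thr.tve else "yellow",
        trajectory=tuple(tuple(p) for p in trajectory) if state.mode == 1 and trajectory else None,
    )


def render_status(status: BiofeedbackStatus) -> str:
    lines = [
        f"state: {status.state_name}",
        f"AVF: {status.avf:7.2f} uV [{status.flexor_band}]",
        f"AVE: {status.ave:7.2f} uV [{status.extensor_band}]",
    ]
    if status.trajectory is not None:
        lines.append(f"trajectory: {len(status.trajectory)} poses")
    return "\n".join(lines)


def _step_fsm(
    s: ModeState, label: Movement, edge: bool, fsm: FsmConfig
) -> tuple[ModeState, ControlCommand]:
    if s.mode == 1:
        return cm.mode1_step(s, label, edge, fsm)
    if s.mode == 2:
        return cm.mode2_step(s, label, edge, fsm)
    return cm.mode3_step(s, label, edge, fsm.dwell_windows)


def run_trial(
    mode: int,
    object_name: str,
    slot: int,
    emg: EmgTrace,
    config: AppConfig | None = None,
    world: WorldState | None = None,
    collect_log: bool = False,
) -> TrialResult | tuple[TrialResult, list[DecisionRecord]]:
    """Run one pick-and-place trial from a raw EMG trace.

    Per decision window: envelope → ON/OFF classification → event-edge
    flag → mode FSM → world command.  The trial ends on success, when the
    target object falls off the table, on the simulated-time limit, or
    when the trace is exhausted (counted as a timeout).

    Movement counts are tallied from segmented events over the windows
    actually consumed, mirroring the control semantics: flexion and
    extension act on every held window (each window is one commanded
    movement, so their counts sum window runs), while co-contraction acts
    once per event.  The co-contraction count reflects switch events
    consumed by the FSM, which is every co-contraction event in modes 1
    and 2 and none in mode 3, where the gesture has no function.
    """
    config = config or default_config()
    if abs(emg.sampling_rate - config.synth.sampling_rate) > 1e-6:
        raise ValueError(
            f"trace sampling rate {emg.sampling_rate} Hz differs from configured "
            f"{config.synth.sampling_rate} Hz"
        )
    rt = config.runtime
    env = condition(emg, rt.lowpass_cutoff_hz, rt.envelope_window_s, rt.envelope_hop_s)
    labels = classify_trace(env, config.thresholds)
    w = world if world is not None else init_world(config.scene)
    state = cm.initial_state(mode, config.fsm, n_objects=len(config.scene.objects))
    hop = rt.envelope_hop_s
    menu_objects = [o.name for o in config.scene.objects]

    records: list[DecisionRecord] = []
    consumed = 0
    n_co_switch = 0
    success = False
    failure = "timeout"
    prev = None
    for i, label in enumerate(labels):
        edge = label != prev
        prev = label
        before = state
        state, cmd = _step_fsm(state, label, edge, config.fsm)
        if label is Movement.COCONTRACTION and edge and mode in (1, 2):
            n_co_switch += 1
        if cmd.verb in ("move", "open_gripper", "close_gripper"):
            apply_command(w, cmd, hop)
        elif cmd.verb == "auto_pick":  # mode 2: nearest object
            try:
                auto_pick(w, None)
            except WorldError:
                pass
            w.time += hop
        elif cmd.verb == "auto_place":  # mode 2: nearest free slot
            try:
                auto_place(w, nearest_free_slot(w))
            except WorldError:
                pass
            w.time += hop
        elif cmd.verb == "select":  # mode 3: dispatch pending auto action
            try:
                if state.pending_auto == "pick":
                    auto_pick(w, menu_objects[cmd.cursor])
                else:
                    auto_place(w, cmd.cursor + 1)
                state = cm.notify_auto_done(state)
            except WorldError:
                state = cm.cancel_pending_auto(state)
            w.time += hop
        else:
            w.time += hop
        consumed = i + 1
        if collect_log:
            records.append(
                DecisionRecord(env.time[i], label, edge, str(before.state.value), cmd.verb, str(state.state.value))
            )
        if check_trial_success(w, object_name, slot):
            success = True
            failure = "none"
            break
        if w.objects[object_name].state is ObjState.FALLEN_OFF:
            failure = "fallen_object"
            break
        if w.time >= rt.timeout_s:
            failure = "timeout"
            break

    events = segment_events(labels[:consumed], env.time[:consumed]) if consumed else []
    n_flex = sum(e.n_windows for e in events if e.kind is Movement.FLEXION)
    n_ext = sum(e.n_windows for e in events if e.kind is Movement.EXTENSION)
    result = TrialResult(
        user_id=config.user_id,
        mode=mode,
        object_name=object_name,
        slot=slot,
        n_flexion=n_flex,
        n_extension=n_ext,
        n_cocontraction=n_co_switch,
        duration_s=float(w.time),
        success=success,
        failure_reason=failure,
    )
    return (result, records) if collect_log else result


# ---------------------------------------------------------------------------
# Scripted ideal participant
# ---------------------------------------------------------------------------

_REST_GAP_S = 0.3
_CO_S = 0.2
_TRIGGER_S = 0.2


class _ScriptBuilder:
    def __init__(self, thr: Thresholds, hop: float):
        self.entries: list[GestureEntry] = []
        self.thr = thr
        self.hop = hop
        self.i_flex = 3.0 * thr.tvf
        self.i_ext = 3.0 * thr.tve
        self.i_co = 3.0 * max(thr.tvf, thr.tve)

    def rest(self, seconds: float) -> None:
        if seconds > 0:
            self.entries.append(GestureEntry("rest", seconds))

    def gesture(self, kind: str, n_windows: int) -> None:
        if n_windows <= 0:
            return
        intensity = {"flexion": self.i_flex, "extension": self.i_ext, "cocontraction": self.i_co}[kind]
        self.entries.append(GestureEntry(kind, n_windows * self.hop, intensity))
        self.rest(_REST_GAP_S)

    def co(self) -> None:
        self.gesture("cocontraction", int(round(_CO_S / self.hop)))

    def move_axis(self, delta: float, step: float) -> None:
        n = int(round(abs(delta) / step))
        if n:
            self.gesture("flexion" if delta < 0 else "extension", n)

    def build(self, trailing_s: float = 0.5) -> GestureScript:
        self.rest(trailing_s)
        return GestureScript(tuple(self.entries))


def oracle_user(
    mode: int,
    object_name: str,
    slot: int,
    world: WorldState | None = None,
    config: AppConfig | None = None,
) -> GestureScript:
    """Compute the minimal gesture script completing a task under a mode.

    Plans open-loop from world geometry and FSM semantics: axis distances
    become runs of motion windows, state switches become co-contraction
    events, and in mode 3 menu navigation becomes cursor events followed
    by selection dwells.  Gesture intensities are placed at three times
    the relevant threshold so detection is unambiguous.
    """
    config = config or default_config()
    w = world.copy() if world is not None else init_world(config.scene)
    cfg = w.config
    if object_name not in w.objects:
        raise WorldError(f"unknown object {object_name!r}")
    obj = w.objects[object_name]
    if obj.state is not ObjState.ON_TABLE:
        raise WorldError(f"object {object_name} is not graspable")
    if w.slots[slot] is not None:
        raise WorldError(f"slot {slot} is occupied")
    sx, sz = cfg.slot_center(slot)
    hop = config.runtime.envelope_hop_s
    b = _ScriptBuilder(config.thresholds, hop)
    b.rest(_REST_GAP_S)
    home = np.array(cfg.home, dtype=float)
    step = cfg.motion_step

    if mode == 1:
        # X → (co) Y → (co) Z → (co) gripper → grasp → back around the cycle
        b.move_axis(obj.pose[0] - home[0], step)  # X: over the object
        b.co()
        b.move_axis(obj.pose[1] - home[1], step)  # Y: descend to grasp height
        b.co()
        b.move_axis(obj.pose[2] - home[2], step)  # Z
        b.co()
        n_close = int(np.ceil((cfg.aperture_max - obj.collider[0]) / cfg.aperture_step)) + 1
        b.gesture("flexion", n_close)  # gripper: close until grasped
        b.co()
        b.move_axis(sx - obj.pose[0], step)  # X: toward the slot
        b.co()
        b.move_axis(cfg.transport_height - obj.pose[1], step)  # Y: lift clear
        b.co()
        b.move_axis(sz - obj.pose[2], step)  # Z
        b.co()
        b.gesture("extension", 2)  # gripper: open → release into the slot
        return b.build()

    if mode == 2:
        pick = "flexion" if config.fsm.pick_gesture is Movement.FLEXION else "extension"
        place = "extension" if pick == "flexion" else "flexion"
        b.move_axis(obj.pose[0] - home[0], step)  # X: over the object
        b.co()
        b.move_axis(obj.pose[2] - home[2], step)  # Z
        b.co()
        b.gesture(pick, int(round(_TRIGGER_S / hop)))  # auto pick (nearest = target)
        b.co()  # pick/place → X
        b.move_axis(sx - obj.pose[0], step)
        b.co()
        b.move_axis(sz - obj.pose[2], step)
        b.co()
        b.gesture(place, int(round(_TRIGGER_S / hop)))  # auto place at nearest slot
        return b.build()

    if mode == 3:
        dwell = config.fsm.dwell_windows
        menu = [o.name for o in cfg.objects]
        obj_idx = menu.index(object_name)
        for _ in range(obj_idx):  # navigate the object menu forward
            b.gesture("extension", int(round(_TRIGGER_S / hop)))
        b.rest(dwell * hop + hop)  # dwell → select object → auto pick
        for _ in range(slot - 1):  # navigate the destination menu
            b.gesture("extension", int(round(_TRIGGER_S / hop)))
        b.rest(dwell * hop + hop)  # dwell → select slot → auto place
        return b.build()

    raise ValueError(f"mode must be 1, 2 or 3, got {mode}")


def default_protocol(scene: SceneConfig | None = None) -> list[tuple[int, str, int]]:
    """The evaluation protocol: three modes × five objects, one slot each."""
    scene = scene or SceneConfig()
    names = [o.name for o in scene.objects]
    return [(mode, name, i + 1) for mode in (1, 2, 3) for i, name in enumerate(names)]


def run_session(
    config: AppConfig | None = None,
    protocol: Sequence[tuple[int, str, int]] | None = None,
    seed: int | None = None,
) -> SessionLog:
    """Run a full oracle-driven session: one trial per protocol entry.

    Each trial starts from a fresh world; its EMG trace is synthesized
    from the oracle gesture script with a per-trial seed derived from
    ``seed``.  Inter-trial pauses are added to the session total time, so
    the total exceeds the sum of trial durations, as in a live session.
    """
    config = config or default_config()
    if protocol is None:
        protocol = default_protocol(config.scene)
    if not protocol:
        raise ValueError("empty protocol")
    base_seed = config.runtime.seed if seed is None else seed
    log = SessionLog(user_id=config.user_id, thresholds=config.thresholds)
    total_s = 0.0
    for k, (mode, obj, slot) in enumerate(protocol):
        script = oracle_user(mode, obj, slot, config=config)
        params = SynthParams(
            sampling_rate=config.synth.sampling_rate,
            baseline_noise=config.synth.baseline_noise,
            band=config.synth.band,
            rise_time=config.synth.rise_time,
            seed=(base_seed * 1000 + k) % (2**31 - 1),
            crosstalk=config.synth.crosstalk,
        )
        trace = synthesize_trace(script, params)
        result = run_trial(mode, obj, slot, trace, config)
        log.trials.append(result)
        total_s += result.duration_s + config.runtime.inter_trial_pause_s
    log.total_time_min = total_s / 60.0
    return log


def report(log: SessionLog, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Build per-mode movement-count tables and the session summary.

    Returns one counts table per mode (rows = objects; flexion, extension
    and co-contraction event counts plus duration and outcome) and a
    one-row summary (total time, thresholds, success rate).  With
    ``out_dir`` set, each table is also written as CSV.
    """
    if not log.trials:
        raise ValueError("empty session log")
    tables: dict[str, pd.DataFrame] = {}
    for mode in sorted({t.mode for t in log.trials}):
        rows = [
            {
                "object": t.object_name,
                "slot": t.slot,
                "flex": t.n_flexion,
                "ext": t.n_extension,
                "co": t.n_cocontraction,
                "duration_s": round(t.duration_s, 1),
                "success": t.success,
            }
            for t in log.trials
            if t.mode == mode
        ]
        tables[f"mode{mode}_counts"] = pd.DataFrame(rows)
    tables["summary"] = pd.DataFrame(
        [
            {
                "user": log.user_id,
                "total_time_min": round(log.total_time_min, 2),
                "tvf_uV": log.thresholds.tvf,
                "tve_uV": log.thresholds.tve,
                "success_rate_pct": round(log.success_rate, 2),
            }
        ]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
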