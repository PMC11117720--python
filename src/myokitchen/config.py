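"""User/session configuration: thresholds, FSM, scene and runtime settings.

Configs are plain dataclasses with YAML round-trip.  Only keys present in
the file override the defaults, so a minimal per-user file can be just::

    user:
      tvf_uV: 20
      tve_uV: 30
    mode: 2
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .control_modes import FsmConfig
from .emg_synthesis import SynthParams
from .kitchen_world import ObjectSpec, SceneConfig
from .onoff_classifier import Movement, Thresholds

__all__ = ["RuntimeConfig", "AppConfig", "default_config", "load_config", "save_config"]


@dataclass(frozen=True)
class RuntimeConfig:
    """Signal-pipeline and trial parameters."""

    lowpass_cutoff_hz: float = 500.0
    envelope_window_s: float = 0.1
    envelope_hop_s: float = 0.1
    timeout_s: float = 600.0  # simulated per-trial time limit
    inter_trial_pause_s: float = 20.0
    seed: int = 0


@dataclass(frozen=True)
class AppConfig:
    """Everything a session needs: who, how, and where."""

    user_id: str = "user"
    thresholds: Thresholds = field(default_factory=lambda: Thresholds(20.0, 30.0))
    mode: int = 1
    fsm: FsmConfig = field(default_factory=FsmConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    runtime: RuntimeConfig = field(default_factory=RuntimeConfig)
    synth: SynthParams = field(default_factory=SynthParams)


def default_config() -> AppConfig:
    return AppConfig()


def _scene_from_dict(d: dict) -> SceneConfig:
    kw = dict(d)
    if "objects" in kw:
        kw["objects"] = tuple(
            ObjectSpec(o["name"], float(o["x"]), float(o["z"]), tuple(o["collider"]))
            for o in kw["objects"]
        )
    for key in ("table_x", "table_z", "home", "slot_centers_x", "slot_centers_z"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return SceneConfig(**kw)


def load_config(path: str | Path) -> AppConfig:
    """Read a YAML (or JSON — YAML is a superset) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw: dict = {}
    if "user" in raw:
        u = raw["user"]
        if "id" in u:
            kw["user_id"] = str(u["id"])
        if "tvf_uV" in u or "tve_uV" in u:
            kw["thresholds"] = Thresholds(float(u["tvf_uV"]), float(u["tve_uV"]))
    if "mode" in raw:
        kw["mode"] = int(raw["mode"])
    if "fsm" in raw:
        f = dict(raw["fsm"])
        f.pop("mode1_cycle", None)  # cycle orders configurable in code only
        f.pop("mode2_cycle", None)
        if "pick_gesture" in f:
            f["pick_gesture"] = Movement(f["pick_gesture"])
        kw["fsm"] = FsmConfig(**f)
    if "scene" in raw:
        kw["scene"] = _scene_from_dict(raw["scene"])
    if "runtime" in raw:
        kw["runtime"] = RuntimeConfig(**raw["runtime"])
    if "synth" in raw:
        s = dict(raw["synth"])
        if "band" in s:
            s["band"] = tuple(s["band"])
        kw["synth"] = SynthParams(**s)
    return AppConfig(**kw)


def save_config(cfg: AppConfig, path: str | Path) -> None:
    doc = {
        "user": {"id": cfg.user_id, "tvf_uV": cfg.thresholds.tvf, "tve_uV": cfg.thresholds.tve},
        "mode": cfg.mode,
        "fsm": {"pick_gesture": cfg.fsm.pick_gesture.value, "dwell_windows": cfg.fsm.dwell_windows},
        "scene": {
            "table_x": list(cfg.scene.table_x),
            "table_z": list(cfg.scene.table_z),
            "home": list(cfg.scene.home),
            "motion_step": cfg.scene.motion_step,
            "aperture_step": cfg.scene.aperture_step,
            "aperture_max": cfg.scene.aperture_max,
            "objects": [
                {"name": o.name, "x": o.x, "z": o.z, "collider": list(o.collider)}
                for o in cfg.scene.objects
            ],
        },
        "runtime": asdict(cfg.runtime),
        "synth": {
            "sampling_rate": cfg.synth.sampling_rate,
            "baseline_noise": cfg.synth.baseline_noise,
            "band": list(cfg.synth.band),
            "rise_time": cfg.synth.rise_time,
            "seed": cfg.synth.seed,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
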