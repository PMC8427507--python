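"""File formats: pose CSV, gait-event JSON, preset and curve tables.

Pose CSV dialect (UTF-8, '.' decimal separator), one row per bone per frame:

    frame,time_s,bone,rx_deg,ry_deg,rz_deg,tx_cm,ty_cm,tz_cm

Gait-event JSON: ``{limb: [{"touch_down_s": t, "lift_off_s": t|null}, ...]}``
where a null lift-off marks the terminal touch-down that closes the last
stride.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import BONES, DOFS, BoneChain
from .stride import GaitEvents, N_PHASES, NormalizedCurve, PHASE_GRID
from .synthetic import DOFTemplate, GaitPreset

POSE_CSV_COLUMNS = (
    "frame",
    "time_s",
    "bone",
    "rx_deg",
    "ry_deg",
    "rz_deg",
    "tx_cm",
    "ty_cm",
    "tz_cm",
)

_CSV_TO_DOF = {
    "rx_deg": "rx",
    "ry_deg": "ry",
    "rz_deg": "rz",
    "tx_cm": "tx",
    "ty_cm": "ty",
    "tz_cm": "tz",
}
_DOF_TO_CSV = {v: k for k, v in _CSV_TO_DOF.items()}


class PoseFormatError(ValueError):
    """Pose CSV violates the documented dialect."""


def write_pose_csv(chain: BoneChain, path) -> None:
    """Write a bone chain to the long-format pose CSV dialect."""
    frames = []
    for bone in BONES:
        if bone not in chain.poses:
            continue
        df = chain.poses[bone]
        out = pd.DataFrame({"frame": np.arange(len(df)), "time_s": df["time_s"]})
        out["bone"] = bone
        for dof, col in _DOF_TO_CSV.items():
            out[col] = df[dof].to_numpy()
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)[list(POSE_CSV_COLUMNS)]
    table.sort_values(["frame", "bone"], inplace=True, kind="stable")
    table.to_csv(path, index=False, float_format="%.10g")


def read_pose_csv(path) -> BoneChain:
    """Read and validate a pose CSV into a world-frame bone chain."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise PoseFormatError(f"{path}: empty pose file") from exc
    missing = [c for c in POSE_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise PoseFormatError(f"{path}: missing columns {missing}")
    unknown = set(table["bone"].unique()) - set(BONES)
    if unknown:
        rows = table.index[table["bone"].isin(unknown)] + 2  # header + 1-based
        raise PoseFormatError(
            f"{path}: unknown bone labels {sorted(unknown)} "
            f"(first at line {rows.min()})"
        )
    numeric_cols = [c for c in POSE_CSV_COLUMNS if c not in ("bone",)]
    bad = table[numeric_cols].isna().any(axis=1)
    if bad.any():
        raise PoseFormatError(
            f"{path}: malformed numeric value at line {int(bad.idxmax()) + 2}"
        )
    frame_sets = {b: set(g["frame"]) for b, g in table.groupby("bone")}
    all_frames = set().union(*frame_sets.values())
    for bone, frames in frame_sets.items():
        missing_frames = sorted(all_frames - frames)
        if missing_frames:
            raise PoseFormatError(
                f"{path}: bone {bone} missing frame(s) {missing_frames[:5]}"
            )
    poses = {}
    times = None
    for bone, group in table.groupby("bone"):
        group = group.sort_values("frame")
        t = group["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise PoseFormatError(f"{path}: non-monotone time for bone {bone}")
        if times is None:
            times = t
        df = pd.DataFrame({"time_s": t})
        for col, dof in _CSV_TO_DOF.items():
            df[dof] = group[col].to_numpy()
        poses[bone] = df.reset_index(drop=True)
    if times is None or len(times) < 2:
        raise PoseFormatError(f"{path}: fewer than 2 frames")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], atol=1e-6):
        raise PoseFormatError(f"{path}: non-uniform frame grid")
    return BoneChain(frame_rate=1.0 / dt[0], poses=poses)


def write_events_json(events: GaitEvents, path) -> None:
    record: dict[str, list[dict]] = {}
    for limb in events.limbs:
        td = events.touch_downs[limb]
        lo = events.lift_offs[limb]
        entries = []
        for i, t in enumerate(td):
            entries.append(
                {
                    "touch_down_s": float(t),
                    "lift_off_s": float(lo[i]) if i < len(lo) else None,
                }
            )
        record[limb] = entries
    Path(path).write_text(json.dumps(record, indent=1), encoding="utf-8")


def read_events_json(path) -> GaitEvents:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    tds = {}
    los = {}
    for limb, entries in data.items():
        tds[limb] = np.array([e["touch_down_s"] for e in entries], dtype=float)
        los[limb] = np.array(
            [e["lift_off_s"] for e in entries if e.get("lift_off_s") is not None],
            dtype=float,
        )
    return GaitEvents(touch_downs=tds, lift_offs=los)


def write_curves_csv(curves: dict[tuple[str, str, int], NormalizedCurve], path) -> None:
    """Long-format normalized-curve table: bone, dof, stride_id, phase, value."""
    rows = []
    for (bone, dof, stride_id), curve in curves.items():
        rows.append(
            pd.DataFrame(
                {
                    "bone": bone,
                    "dof": dof,
                    "stride_id": stride_id,
                    "phase_pct": PHASE_GRID,
                    "value": curve.values,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_curves_csv(path) -> dict[tuple[str, str, int], NormalizedCurve]:
    table = pd.read_csv(path)
    out = {}
    for (bone, dof, stride_id), group in table.groupby(["bone", "dof", "stride_id"]):
        values = group.sort_values("phase_pct")["value"].to_numpy()
        if len(values) != N_PHASES:
            raise ValueError(f"curve {bone}/{dof}/{stride_id}: wrong grid length")
        out[(bone, dof, int(stride_id))] = NormalizedCurve(values=values)
    return out


def _template_to_flat(tmpl: DOFTemplate) -> dict:
    return {
        "anchors": [[p, v] for p, v in tmpl.anchors],
        "rom": tmpl.rom,
        "phase_jitter_sd": tmpl.phase_jitter_sd,
        "rom_jitter_sd": tmpl.rom_jitter_sd,
        "noise_sd": tmpl.noise_sd,
        "drift_per_stride": tmpl.drift_per_stride,
    }


def write_preset_yaml(preset: GaitPreset, path) -> None:
    data = {
        "name": preset.name,
        "gait": preset.gait,
        "duty_factor": preset.duty_factor,
        "stride_duration_s": preset.stride_duration_s,
        "duty_jitter_sd": preset.duty_jitter_sd,
        "limb_phase_offsets": dict(preset.limb_phase_offsets),
        "templates": {
            bone: {dof: _template_to_flat(t) for dof, t in per_bone.items()}
            for bone, per_bone in preset.templates.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def read_preset_yaml(path) -> GaitPreset:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    templates = {
        bone: {
            dof: DOFTemplate(
                anchors=tuple((p, v) for p, v in t["anchors"]),
                rom=t["rom"],
                phase_jitter_sd=t.get("phase_jitter_sd", 0.0),
                rom_jitter_sd=t.get("rom_jitter_sd", 0.0),
                noise_sd=t.get("noise_sd", 0.0),
                drift_per_stride=t.get("drift_per_stride", 0.0),
            )
            for dof, t in per_bone.items()
        }
        for bone, per_bone in data["templates"].items()
    }
    return GaitPreset(
        name=data["name"],
        gait=data["gait"],
        duty_factor=data["duty_factor"],
        stride_duration_s=data["stride_duration_s"],
        limb_phase_offsets=data["limb_phase_offsets"],
        templates=templates,
        duty_jitter_sd=data.get("duty_jitter_sd", 0.01),
    )
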