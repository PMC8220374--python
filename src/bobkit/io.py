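"""File formats, model configuration and run manifests.

All numeric output uses 17 significant digits so that every format
round-trips losslessly at double precision.  Undefined margins (the LIP
viable margins) are serialized as the explicit token ``"undefined"``,
never as zero or a missing value.

Model parameter files are flat YAML with SI units; see
``bobkit/fixtures/*.yaml`` for the shipped reference sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bob import BoB, BoBPoint, OptimizationSettings, UNBOUNDED
from .geometry import BoundaryMargins
from .lip import UNDEFINED
from .margins import EmosSeries, TargetSpec, Trajectory
from .models import (
    AnthropometricSet,
    BipedModel,
    ModelKind,
    dof4_model,
    dof5_model,
    lip_model,
)

__all__ = [
    "SchemaError",
    "load_model_config",
    "save_model_config",
    "model_hash",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_bob_csv",
    "read_bob_csv",
    "write_emos_csv",
    "write_margins_json",
    "read_margins_json",
    "write_targets_json",
    "write_manifest",
    "fixture_path",
]

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A model configuration file failed validation; names the field."""


def fixture_path(name: str) -> Path:
    """Path of a shipped fixture file (``lip``, ``dof4`` or ``dof5``)."""
    p = Path(__file__).parent / "fixtures" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no shipped fixture named {name!r}")
    return p


# ---------------------------------------------------------------------------
# Model configuration
# ---------------------------------------------------------------------------


def _require(cfg: dict, field: str, kind=float, positive=False):
    if field not in cfg:
        raise SchemaError(f"missing field: {field}")
    val = cfg[field]
    try:
        if kind is float:
            val = float(val)
        elif kind is list:
            val = [float(v) for v in val]
    except (TypeError, ValueError):
        raise SchemaError(f"field {field}: expected {kind.__name__}") from None
    if positive:
        vals = val if isinstance(val, list) else [val]
        if any(v <= 0 for v in vals):
            raise SchemaError(f"field {field}: values must be positive")
    return val


def load_model_config(path) -> BipedModel:
    """Construct a validated :class:`BipedModel` from a YAML parameter file."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("model file must contain a mapping")
    kind = cfg.get("kind")
    try:
        kind = ModelKind(kind)
    except ValueError:
        raise SchemaError(f"field kind: must be one of "
                          f"{[k.value for k in ModelKind]}, got {kind!r}") from None
    g = _require(cfg, "g", positive=True) if "g" in cfg else 9.81
    if kind is ModelKind.LIP:
        fl = _require(cfg, "foot_length", positive=True)
        ybar = _require(cfg, "standing_com_height", positive=True)
        return lip_model(fl=fl, ybar=ybar, g=g)
    lengths = _require(cfg, "segment_lengths", list, positive=True)
    masses = _require(cfg, "segment_masses", list, positive=True)
    offsets = _require(cfg, "com_offsets", list)
    inertias = _require(cfg, "inertias", list)
    fl = _require(cfg, "foot_length", positive=True)
    geom = _require(cfg, "foot_geometry", list, positive=True)
    if len(geom) != 3:
        raise SchemaError("field foot_geometry: needs heel-ankle, "
                          "ankle-metatarsal, metatarsal-toe distances")
    foot_mass = _require(cfg, "foot_mass", positive=True)
    ybar = _require(cfg, "standing_com_height", positive=True)
    angle_limits = np.asarray(_require_nested(cfg, "joint_angle_limits"))
    torque_limits = np.asarray(_require_nested(cfg, "joint_torque_limits"))
    try:
        params = AnthropometricSet(
            segment_lengths=np.asarray(lengths), segment_masses=np.asarray(masses),
            com_offsets=np.asarray(offsets), inertias=np.asarray(inertias),
            joint_angle_limits=angle_limits, joint_torque_limits=torque_limits,
            foot_length=fl, foot_geometry=tuple(geom), foot_mass=foot_mass,
            standing_com_height=ybar)
    except ValueError as exc:
        raise SchemaError(str(exc)) from None
    if kind is ModelKind.DOF4:
        return dof4_model(params, g=g)
    return dof5_model(params, g=g)


def _require_nested(cfg, field):
    if field not in cfg:
        raise SchemaError(f"missing field: {field}")
    try:
        rows = [[float(a), float(b)] for a, b in cfg[field]]
    except (TypeError, ValueError):
        raise SchemaError(f"field {field}: expected a list of (min, max) pairs") from None
    return rows


def model_to_dict(model: BipedModel) -> dict:
    d = {"kind": model.kind.value, "g": model.g,
         "foot_length": model.fl, "standing_com_height": model.ybar}
    if model.params is not None:
        p = model.params
        d.update(
            segment_lengths=p.segment_lengths.tolist(),
            segment_masses=p.segment_masses.tolist(),
            com_offsets=p.com_offsets.tolist(),
            inertias=p.inertias.tolist(),
            joint_angle_limits=p.joint_angle_limits.tolist(),
            joint_torque_limits=p.joint_torque_limits.tolist(),
            foot_geometry=list(p.foot_geometry),
            foot_mass=p.foot_mass,
        )
    return d


def save_model_config(model: BipedModel, path):
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


def model_hash(model: BipedModel) -> str:
    payload = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_TRAJ_COLS = ["t", "x", "y", "xdot", "ydot", "stance_intact"]


def write_trajectory_csv(traj: Trajectory, path):
    df = pd.DataFrame({
        "t": traj.t, "x": traj.x, "y": traj.y,
        "xdot": traj.xdot, "ydot": traj.ydot,
        "stance_intact": traj.stance_intact.astype(int),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"nondimensional": bool(traj.nondimensional)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory file missing columns: {missing}")
    meta_path = Path(str(path) + ".meta.json")
    nondim = False
    if meta_path.exists():
        nondim = bool(json.loads(meta_path.read_text()).get("nondimensional", False))
    return Trajectory(t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
                      xdot=df["xdot"].to_numpy(), ydot=df["ydot"].to_numpy(),
                      stance_intact=df["stance_intact"].to_numpy().astype(bool),
                      nondimensional=nondim)


# ---------------------------------------------------------------------------
# BoB, margins, eMOS, targets
# ---------------------------------------------------------------------------


def write_bob_csv(bob: BoB, path, model: BipedModel | None = None):
    rows = []
    for p in bob.points:
        rows.append({
            "x": p.x, "ybar": p.ybar,
            "xdot_min": p.xdot_min if p.feasible else np.nan,
            "xdot_max": p.xdot_max if p.feasible else np.nan,
            "ydot_at_min": p.ydot_at_min if p.feasible else np.nan,
            "ydot_at_max": p.ydot_at_max if p.feasible else np.nan,
            "feasible": int(p.feasible),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "fl": bob.fl, "ybar": bob.ybar, "omega": bob.omega,
        "nondimensional": bool(bob.nondimensional),
        "domain": _margin_token(bob.domain),
        "settings": dataclasses.asdict(bob.settings) if bob.settings else None,
        "version": __version__,
    }
    if model is not None:
        meta["model_hash"] = model_hash(model)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_bob_csv(path) -> BoB:
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    points = []
    for _, r in df.iterrows():
        feasible = bool(int(r["feasible"]))
        if feasible:
            points.append(BoBPoint(x=r["x"], ybar=r["ybar"], feasible=True,
                                   xdot_min=r["xdot_min"], xdot_max=r["xdot_max"],
                                   ydot_at_min=r["ydot_at_min"],
                                   ydot_at_max=r["ydot_at_max"]))
        else:
            points.append(BoBPoint(x=r["x"], ybar=r["ybar"], feasible=False))
    settings = (OptimizationSettings(**meta["settings"])
                if meta.get("settings") else None)
    domain = meta.get("domain")
    if isinstance(domain, list):
        domain = tuple(domain)
    return BoB(points=points, fl=meta["fl"], ybar=meta["ybar"], omega=meta["omega"],
               nondimensional=meta["nondimensional"], settings=settings, domain=domain)


def _margin_token(v):
    if v is UNDEFINED:
        return "undefined"
    if v == UNBOUNDED:
        return UNBOUNDED
    return v


def _margin_from_token(v):
    if v == "undefined":
        return UNDEFINED
    return v


def write_margins_json(margins: BoundaryMargins, path):
    d = {
        "reachable_post": margins.reachable_post,
        "reachable_ant": margins.reachable_ant,
        "viable_post": _margin_token(margins.viable_post),
        "viable_ant": _margin_token(margins.viable_ant),
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_margins_json(path) -> BoundaryMargins:
    d = json.loads(Path(path).read_text())
    return BoundaryMargins(
        reachable_post=d["reachable_post"], reachable_ant=d["reachable_ant"],
        viable_post=_margin_from_token(d["viable_post"]),
        viable_ant=_margin_from_token(d["viable_ant"]))


def write_emos_csv(traj: Trajectory, series: EmosSeries, path):
    df = pd.DataFrame({
        "t": traj.t,
        "e_upper": [r.e_upper for r in series],
        "e_lower": [r.e_lower for r in series],
        "critical": [r.critical for r in series],
        "critical_side": [r.critical_side.value for r in series],
        "extrapolated": [int(r.extrapolated) for r in series],
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_targets_json(targets: list[TargetSpec], path):
    rows = []
    for t in targets:
        rows.append({
            "category": t.category.value,
            "x": t.target_state.x, "y": t.target_state.y,
            "xdot": t.target_state.xdot, "ydot": t.target_state.ydot,
            "tolerance": t.tolerance,
            "progression_index": t.progression_index,
            "intended_emos": t.intended_emos,
        })
    Path(path).write_text(json.dumps(rows, indent=1))


def write_manifest(path, *, command: str, inputs: dict, seed=None, settings=None):
    """Record everything needed to reproduce a run next to its outputs."""
    manifest = {
        "command": command,
        "inputs": inputs,
        "seed": seed,
        "settings": dataclasses.asdict(settings) if settings is not None else None,
        "version": __version__,
        "numpy": np.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
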