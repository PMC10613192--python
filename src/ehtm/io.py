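"""Material-card and scenario I/O.

A material card is a flat INI-style text file with four blocks mirroring
the keyword-card fields of the muscle material: ``[META]`` (muscle name,
unit system tag), ``[HILL]`` (mechanical constants), ``[ACT]``
(activation mode + constants) and ``[CTRL]`` (controller mode +
constants).  Only the muscle-specific values F_MAX, L_CE_OPT and L_SEE_0
are mandatory; missing non-specific fields fill from the shipped
kg-mm-ms-kN defaults with a logged notice.  Stimulation schedules are
referenced as time-value CSV tables.

Scenario configs are small YAML files naming a rig fixture, a protocol
and numerical settings; ``run_scenario`` executes them and writes the
trajectory CSV, a metrics JSON and a log with the config digest.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .activation import ActivationParams
from .control import ControllerConfig, Schedule
from .evaluation import kinematic_metrics
from .fixtures import FixtureSpec, make_rig
from .muscle import MuscleParams
from .rigs import simulate_mtu_bench, simulate_reflex_drop, simulate_rig

__all__ = [
    "MaterialCard",
    "CardError",
    "read_material_card",
    "write_material_card",
    "read_stim_table",
    "write_stim_table",
    "run_scenario",
]

log = logging.getLogger("ehtm")

_HILL_FIELDS = {
    "F_MAX": "F_max", "L_CE_OPT": "l_CE_opt", "L_SEE_0": "l_SEE_0",
    "DW_DES": "dW_des", "DW_ASC": "dW_asc", "NU_CE_DES": "nu_CE_des",
    "NU_CE_ASC": "nu_CE_asc", "A_REL_0": "A_rel_0", "B_REL_0": "B_rel_0",
    "F_ECC": "F_ecc", "S_ECC": "S_ecc", "L_PEE_0": "L_PEE_0",
    "NU_PEE": "nu_PEE", "F_PEE": "F_PEE", "DU_SEE_NLL": "dU_SEE_nll",
    "DU_SEE_L": "dU_SEE_l", "DF_SEE_0": "dF_SEE_0", "D_SDE": "D_SDE",
    "R_SDE": "R_SDE",
}
_ACT_FIELDS = {
    "MODE": "mode", "Q0": "q0", "C": "c", "ETA": "eta",
    "NU_HATZE": "nu_hatze", "M_HATZE": "m_hatze", "TAU_Q": "tau_q",
    "BETA_Q": "beta_q",
}
_CTRL_FIELDS = {
    "MODE": "mode", "KP": "k_p", "KD": "k_d", "DELTA": "delta",
    "LAMBDA": "lam", "LAMBDA_DOT": "lam_dot", "OMEGA": "omega",
    "TAU": "tau_reflex", "TCONTR": "t_contr", "L_CE_REF": "l_CE_ref",
    "STIM_FILE": None,  # handled separately
}
_SPECIFIC = ("F_MAX", "L_CE_OPT", "L_SEE_0")


class CardError(ValueError):
    """Material-card parse or validation error."""


@dataclasses.dataclass(frozen=True)
class MaterialCard:
    """Parsed material card: muscle + activation + controller blocks."""

    name: str
    units: str
    hill: MuscleParams
    act: ActivationParams
    ctrl: ControllerConfig
    stim_file: str | None = None


def _parse_float(section: str, key: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise CardError(
            f"[{section}] {key}: {raw!r} is not a number"
        ) from None


def read_material_card(path) -> MaterialCard:
    """Parse and validate a material card file.

    Unknown keys, non-numeric or out-of-range values and missing
    muscle-specific parameters raise :class:`CardError` naming the block
    and key (syntax errors carry the line number); missing non-specific
    fields fill from defaults with a logged notice.
    """
    path = Path(path)
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep key case
    try:
        with open(path) as fh:
            cp.read_file(fh, source=str(path))
    except configparser.Error as exc:
        raise CardError(f"{path}: {exc}") from None

    if "META" not in cp or "UNITS" not in cp["META"]:
        raise CardError(f"{path}: [META] UNITS tag must be declared")
    units = cp["META"]["UNITS"].strip()
    name = cp["META"].get("NAME", path.stem).strip()

    hill_kwargs = {}
    for key, raw in cp["HILL"].items() if "HILL" in cp else ():
        if key not in _HILL_FIELDS:
            raise CardError(f"[HILL] unknown key {key!r}")
        hill_kwargs[_HILL_FIELDS[key]] = _parse_float("HILL", key, raw)
    for key in _SPECIFIC:
        if _HILL_FIELDS[key] not in hill_kwargs:
            raise CardError(f"[HILL] missing muscle-specific parameter {key}")
    filled = [k for k in _HILL_FIELDS if k not in _SPECIFIC
              and _HILL_FIELDS[k] not in hill_kwargs]
    if filled:
        log.info("%s: non-specific fields %s filled from defaults",
                 path.name, ", ".join(sorted(filled)))
    try:
        hill = MuscleParams(**hill_kwargs)
    except ValueError as exc:
        raise CardError(f"[HILL] {exc}") from None

    act_kwargs = {}
    for key, raw in cp["ACT"].items() if "ACT" in cp else ():
        if key not in _ACT_FIELDS:
            raise CardError(f"[ACT] unknown key {key!r}")
        field = _ACT_FIELDS[key]
        act_kwargs[field] = raw.strip() if field == "mode" else _parse_float("ACT", key, raw)
    try:
        act = ActivationParams(**act_kwargs)
    except ValueError as exc:
        raise CardError(f"[ACT] {exc}") from None

    ctrl_kwargs = {}
    stim_file = None
    for key, raw in cp["CTRL"].items() if "CTRL" in cp else ():
        if key not in _CTRL_FIELDS:
            raise CardError(f"[CTRL] unknown key {key!r}")
        if key == "STIM_FILE":
            stim_file = raw.strip()
            continue
        field = _CTRL_FIELDS[key]
        ctrl_kwargs[field] = raw.strip() if field == "mode" else _parse_float("CTRL", key, raw)
    try:
        ctrl = ControllerConfig(**ctrl_kwargs)
    except ValueError as exc:
        raise CardError(f"[CTRL] {exc}") from None
    if stim_file is not None:
        sched = read_stim_table(path.parent / stim_file)
        ctrl = dataclasses.replace(ctrl, stim_open=sched)

    return MaterialCard(name=name, units=units, hill=hill, act=act,
                        ctrl=ctrl, stim_file=stim_file)


def write_material_card(card: MaterialCard, path) -> None:
    """Write a card so that read(write(card)) round-trips losslessly."""
    inv_hill = {v: k for k, v in _HILL_FIELDS.items()}
    inv_act = {v: k for k, v in _ACT_FIELDS.items()}
    inv_ctrl = {v: k for k, v in _CTRL_FIELDS.items() if v}
    lines = ["[META]", f"NAME = {card.name}", f"UNITS = {card.units}", ""]
    lines.append("[HILL]")
    for field in dataclasses.fields(card.hill):
        lines.append(f"{inv_hill[field.name]} = {getattr(card.hill, field.name)!r}")
    lines += ["", "[ACT]"]
    for field in dataclasses.fields(card.act):
        val = getattr(card.act, field.name)
        lines.append(f"{inv_act[field.name]} = {val if field.name == 'mode' else repr(val)}")
    lines += ["", "[CTRL]", f"MODE = {card.ctrl.mode}"]
    for fname in ("k_p", "k_d", "delta", "lam", "lam_dot", "omega",
                  "tau_reflex", "t_contr", "l_CE_ref"):
        val = getattr(card.ctrl, fname)
        if isinstance(val, Schedule) or val is None:
            continue
        lines.append(f"{inv_ctrl[fname]} = {val!r}")
    if card.stim_file:
        lines.append(f"STIM_FILE = {card.stim_file}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_stim_table(path) -> Schedule:
    """Read a time-value CSV stimulation table into a Schedule."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CardError(f"{path}: stimulation table needs two columns")
    return Schedule.from_pairs(list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_stim_table(schedule: Schedule, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_ms": schedule.times, "stim": schedule.values}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_scenario(config_path, out_dir) -> dict:
    """Run a YAML scenario and write artifacts.

    The scenario names a rig fixture (or the MTU bench), a protocol and
    numerical settings.  Writes ``<name>.csv`` (trajectories),
    ``<name>_metrics.json`` and ``<name>.log`` into ``out_dir``; returns
    the metrics dict.  Raises on schema violations without writing
    partial outputs.
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict) or "kind" not in cfg or "name" not in cfg:
        raise ValueError(f"{config_path}: scenario needs 'kind' and 'name'")
    kind = cfg["kind"]
    name = cfg["name"]
    dt = float(cfg.get("dt", 0.25))
    duration = float(cfg.get("duration", 1000.0))
    seed = int(cfg.get("seed", 0))

    if kind == "bench":
        from .fixtures import default_muscle

        p, act = default_muscle(cfg.get("muscle", "generic"))
        sched = None
        if "stim_table" in cfg:
            sched = read_stim_table(config_path.parent / cfg["stim_table"])
        result = simulate_mtu_bench(
            cfg.get("protocol", "isometric"), p, act, duration, dt,
            l_mtu=cfg.get("l_mtu"), stim_schedule=sched,
            release_time=cfg.get("release_time"), load=float(cfg.get("load", 0.0)),
        )
        results = [result]
    elif kind == "rig":
        spec = FixtureSpec(cfg["rig"], seed, cfg.get("overrides", {}))
        rig = make_rig(spec)
        if "controllers" in cfg:
            ctrls = [_ctrl_from_dict(c) for c in cfg["controllers"]]
            rig = rig.with_controllers(ctrls)
        results = [simulate_rig(rig, duration, dt,
                                record_every=int(cfg.get("record_every", 1)))]
    elif kind == "reflex_sweep":
        spec = FixtureSpec(cfg.get("rig", "drop_mass"), seed,
                           cfg.get("overrides", {}))
        rig = make_rig(spec)
        results = simulate_reflex_drop(rig, cfg.get("omega_sweep", [0.03]),
                                       duration, dt)
    else:
        raise ValueError(f"{config_path}: unknown scenario kind {kind!r}")

    out_dir.mkdir(parents=True, exist_ok=True)
    digest = _config_digest(cfg)
    metrics: dict = {"scenario": name, "config_digest": digest, "runs": []}
    for i, res in enumerate(results):
        suffix = f"_{i}" if len(results) > 1 else ""
        res.write_csv(out_dir / f"{name}{suffix}.csv")
        m = kinematic_metrics(res, switch_time=cfg.get("switch_time"))
        m.update({k: v for k, v in res.meta.items()
                  if isinstance(v, (int, float, str))})
        metrics["runs"].append(m)
    (out_dir / f"{name}_metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / f"{name}.log").write_text(
        f"scenario={name}\nconfig_digest={digest}\nseed={seed}\n"
        f"dt={dt}\nversion={__version__}\n"
    )
    return metrics


def _ctrl_from_dict(d: dict) -> ControllerConfig:
    d = dict(d)
    if "stim_open" in d:
        so = d["stim_open"]
        d["stim_open"] = (
            Schedule.from_pairs(so) if isinstance(so, list)
            else Schedule.constant(float(so))
        )
    if isinstance(d.get("lam"), list):
        d["lam"] = Schedule.from_pairs(d["lam"])
    return ControllerConfig(**d)
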