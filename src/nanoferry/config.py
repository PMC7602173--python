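"""YAML/JSON configuration blocks for carriers, environments and scenarios.

Lengths in config files are metres (SI) unless the key ends in a unit
suffix; the carrier block mirrors the constructor of
:func:`nanoferry.geometry.build_carrier`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dynamics import ControllerGains, Environment
from .geometry import CHI_BEAD_DEFAULT, CarrierProperties, build_carrier
from .synthetic import Target, make_target

#: carrier used by examples and sweeps when a config does not say otherwise:
#: a 100 nm x 10 nm functionalized tube with a magnetite-like composite
#: density and the standard bead susceptibility
DEFAULT_CARRIER_CONFIG: Mapping[str, float] = {
    "L_cnt": 100e-9,
    "r_cnt": 10e-9,
    "rho_p": 5000.0,
    "chi_bead": CHI_BEAD_DEFAULT,
}


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def carrier_from_config(cfg: Mapping[str, Any] | None = None) -> CarrierProperties:
    cfg = dict(DEFAULT_CARRIER_CONFIG if cfg is None else cfg)
    return build_carrier(
        L_cnt=float(cfg["L_cnt"]),
        r_cnt=float(cfg["r_cnt"]),
        rho_p=float(cfg["rho_p"]),
        chi_bead=float(cfg.get("chi_bead", CHI_BEAD_DEFAULT)),
        d_p=float(cfg["d_p"]) if "d_p" in cfg else None,
    )


def environment_from_config(cfg: Mapping[str, Any] | None = None) -> Environment:
    cfg = dict(cfg or {})
    return Environment(
        mu_visc=float(cfg.get("mu_visc", 1e-3)),
        rho_fluid=float(cfg.get("rho_fluid", 1000.0)),
        u_fluid=float(cfg.get("u_fluid", 0.0)),
        g=float(cfg.get("g", 9.81)),
    )


def scenario_from_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    """Assemble the pieces of a closed-loop control scenario.

    Expected keys: carrier, environment (optional), alpha, gains {m1, m2},
    target {type, amplitude, t_final}, t_final, dt.
    """
    carrier = carrier_from_config(cfg.get("carrier"))
    env = environment_from_config(cfg.get("environment"))
    gains_cfg = cfg["gains"]
    gains = ControllerGains(m1=float(gains_cfg["m1"]), m2=float(gains_cfg["m2"]))
    tcfg = cfg["target"]
    target: Target = make_target(
        tcfg.get("type", "step"), float(tcfg["amplitude"]), float(tcfg["t_final"])
    )
    return {
        "carrier": carrier,
        "env": env,
        "alpha": float(cfg["alpha"]),
        "gains": gains,
        "target": target,
        "t_final": float(cfg.get("t_final", target.t_final)),
        "dt": float(cfg["dt"]),
    }
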