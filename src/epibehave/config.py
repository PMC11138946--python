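"""YAML run-configuration loading for the command-line interface.

A run config has the shape::

    params:   {beta0: 1.0, pi: 0.5, kappa: 0.9, tau: 3}      # DiseaseParams fields
    profiles:
      m1: {preset: "0", alpha: 0.1}                          # or explicit weights
      p1: {a: 20, e: 10, alpha: 0.1, m0: 0.05}
    initial:  {S_m1: 49998, S_p1: 49998, E: 2, Ia: 1, Is: 1} # StateVector fields
    horizon:  1000
    solver:   {rtol: 1.0e-8, output_dt: 0.5}                 # SolverSettings fields

All blocks are optional; omitted fields fall back to the defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .behavior import BehaviorProfile, preset_profile
from .dde import SolverSettings
from .epidemic import DiseaseParams, StateVector

__all__ = ["load_run_config"]


def _profile_from_block(block: dict) -> BehaviorProfile:
    block = dict(block)
    if "preset" in block:
        name = block.pop("preset")
        return preset_profile(name, **block)
    return BehaviorProfile(**block)


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run config into model objects.

    Returns a dict with keys ``profiles`` (pair), ``params``, ``initial``,
    ``horizon`` and ``settings``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = DiseaseParams(**(raw.get("params") or {}))
    prof_raw = raw.get("profiles") or {}
    if prof_raw:
        m1 = _profile_from_block(prof_raw.get("m1") or prof_raw.get("-1") or {"preset": "0"})
        p1 = _profile_from_block(prof_raw.get("p1") or prof_raw.get("1") or {"preset": "0"})
    else:
        m1 = p1 = preset_profile("0")
    initial = StateVector(**(raw.get("initial") or {}))
    settings = SolverSettings(**(raw.get("solver") or {}))
    return {
        "profiles": (m1, p1),
        "params": params,
        "initial": initial,
        "horizon": float(raw.get("horizon", 1000.0)),
        "settings": settings,
    }
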