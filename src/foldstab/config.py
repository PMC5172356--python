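"""Configuration defaults and YAML loading.

A single nested mapping carries the spin-system constants, spectrometer
field, random seed, and fit options used across the pipeline.  CLI flags
override config values; config values override these defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Mapping

import yaml

DEFAULTS: dict = {
    "seed": 12345,
    "field_mhz": 600.13,
    "constants": {
        # rad s^-1 T^-1; 15N gamma is negative
        "gamma_h": 2.6752218744e8,
        "gamma_n": -2.7116e7,
        "r_nh_angstrom": 1.02,
        "delta_sigma_ppm": -172.0,
    },
    "fit": {
        "mc_iterations": 500,
        "welch": False,           # pooled-variance Student t by default
    },
    "csp": {
        "nitrogen_weight": 0.14,
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Return DEFAULTS deep-merged with a YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(Path(path)) as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg
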