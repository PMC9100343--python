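"""YAML run configuration: one document naming inputs, choices and seeds."""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "write_config"]

DEFAULTS: dict = {
    "run_dir": ".",
    "epochs": ["2000", "2010", "2020"],
    "weights": {
        # "bundled" (published QTP table), "table" (CSV columns), or
        # "ahp_matrix" (square judgment-matrix CSV; entropy comes from data)
        "source": "bundled",
        "path": None,
    },
    "standardization": {"minmax_policy": "global"},
    "classification": {"mode": "geometric_interval", "K": 5, "breaks": None},
    "elevation": {"n_points": 1000, "band_width_m": 50.0, "grid_step_m": None},
    "shdi_window_radius": 5,
    "seed": 0,
    "simulate": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    """Load a run config, merging over the documented defaults.

    Relative paths inside the document resolve against the config file's
    directory; the resolved ``run_dir`` is stored back as absolute.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    cfg = _merge(DEFAULTS, doc)
    base = path.parent
    cfg["run_dir"] = str((base / cfg["run_dir"]).resolve())
    if cfg["weights"].get("path"):
        cfg["weights"]["path"] = str((base / cfg["weights"]["path"]).resolve())
    cfg["epochs"] = [str(e) for e in cfg["epochs"]]
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
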