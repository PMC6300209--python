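"""YAML configuration loading for the CLI."""

from __future__ import annotations


import yaml

from .geometry import BarnGeometry, GridSpec, MilkingWindow, Rect
from .pipeline import RunConfig
from .simulate import SimulationParams


def _rect(d) -> Rect:
    return Rect(d["xmin"], d["xmax"], d["ymin"], d["ymax"])


def geometry_from_dict(d: dict) -> BarnGeometry:
    kwargs = {}
    if "barn" in d:
        kwargs["barn"] = _rect(d["barn"])
    if "zones" in d:
        kwargs["zones"] = {k: _rect(v) for k, v in d["zones"].items()}
    if "milking" in d:
        kwargs["milking"] = tuple(
            MilkingWindow(
                w["start_hour"], w.get("start_minute", 0), w.get("duration_min", 90.0)
            )
            for w in d["milking"]
        )
    return BarnGeometry(**kwargs)


def grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(**d)


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; absent keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    simple = {
        "out_dir",
        "locations_path",
        "metadata_path",
        "smoothing_window",
        "smooth_first",
        "max_gap_s",
        "full_level",
        "core_level",
        "fidelity_scheme",
        "classifier_max_size",
        "max_outlier_removals",
        "seed",
    }
    for k in simple & set(raw):
        kwargs[k] = raw[k]
    if "geometry" in raw:
        kwargs["geometry"] = geometry_from_dict(raw["geometry"])
    if "grid" in raw:
        kwargs["grid"] = grid_from_dict(raw["grid"])
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        if "milking" in sim:
            sim["milking"] = tuple(
                MilkingWindow(
                    w["start_hour"],
                    w.get("start_minute", 0),
                    w.get("duration_min", 90.0),
                )
                for w in sim["milking"]
            )
        kwargs["sim_params"] = SimulationParams(**sim)
    return RunConfig(**kwargs)


def default_config_yaml() -> str:
    """A commented starter configuration."""
    cfg = RunConfig()
    return yaml.safe_dump(
        {
            "out_dir": cfg.out_dir,
            "locations_path": None,
            "metadata_path": None,
            "smoothing_window": cfg.smoothing_window,
            "max_gap_s": cfg.max_gap_s,
            "full_level": cfg.full_level,
            "core_level": cfg.core_level,
            "fidelity_scheme": cfg.fidelity_scheme,
            "classifier_max_size": cfg.classifier_max_size,
            "seed": cfg.seed,
            "simulation": {
                "n_cows": 20,
                "n_days": 5,
                "sample_rate": 0.125,
            },
        },
        sort_keys=False,
    )
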