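"""End-to-end orchestration: locations -> features -> screen -> classifier.

``run_study`` composes the preparation, UD, metrics, fidelity, screening
and classification stages, writes all artefact tables as delimited text,
and records a JSON manifest (config snapshot, per-stage counts, seed) so a
run is an auditable pure function of (config, seed, inputs).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import candidate_features, ranking_table, select_logistic
from .fidelity import FIDELITY_CONTEXTS, fidelity_battery
from .geometry import BarnGeometry, GridSpec
from .metrics import daily_uds_for_cow, features_table, summarize_cow
from .prep import Trajectory, prepare, read_locations, write_locations
from .screen import screen_all
from .simulate import SimulationParams, generate_herd, read_metadata, write_metadata


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    out_dir: str = "barnspace_run"
    locations_path: str | None = None  # None => simulate
    metadata_path: str | None = None
    geometry: BarnGeometry = field(default_factory=BarnGeometry)
    grid: GridSpec = field(default_factory=GridSpec)
    smoothing_window: int = 15
    smooth_first: bool = True
    max_gap_s: float = 40.0
    full_level: float = 0.95
    core_level: float = 0.50
    fidelity_scheme: str = "consecutive"
    classifier_max_size: int = 3
    max_outlier_removals: int = 2
    seed: int = 0
    sim_params: SimulationParams | None = None

    @property
    def simulate(self) -> bool:
        return self.locations_path is None

    def snapshot(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, (tuple, list)):
                return [enc(x) for x in v]
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artefact bundle as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # --- inputs ---------------------------------------------------------
    try:
        if config.simulate:
            params = config.sim_params or SimulationParams(seed=config.seed)
            if params.seed != config.seed:
                params = dataclasses.replace(params, seed=config.seed)
            trajectories, meta_list = generate_herd(params, config.geometry)
            write_locations(trajectories, out / "locations.csv")
            write_metadata(meta_list, out / "metadata.csv")
            metadata = read_metadata(out / "metadata.csv")
        else:
            trajectories = read_locations(config.locations_path)
            if config.metadata_path is None:
                raise ValueError("metadata_path required in non-simulate mode")
            metadata = read_metadata(config.metadata_path)
    except Exception as e:  # noqa: BLE001 - stage attribution
        _write_manifest(out, config, counts, failed_stage="trajectory_prep")
        raise StageError("trajectory_prep", e) from e
    counts["cows"] = len(trajectories)

    # --- prep + UD + metrics + fidelity ---------------------------------
    try:
        summaries = []
        fidelity_rows = []
        retained = excluded = 0
        for traj in trajectories:
            parts = prepare(
                traj,
                config.geometry,
                window=config.smoothing_window,
                smooth_first=config.smooth_first,
            )
            uds = daily_uds_for_cow(parts, config.grid)
            s = summarize_cow(
                parts,
                uds,
                config.geometry,
                config.grid,
                max_gap_s=config.max_gap_s,
                full_level=config.full_level,
                core_level=config.core_level,
            )
            battery = fidelity_battery(
                uds, config.geometry, scheme=config.fidelity_scheme
            )
            for name, value in battery.items():
                setattr(s, name, value)
                region, level = FIDELITY_CONTEXTS[name]
                fidelity_rows.append(
                    {
                        "cow_id": traj.cow_id,
                        "region": region,
                        "level": level,
                        "scheme": config.fidelity_scheme,
                        "score": value,
                        "n_pairs": sum(1 for u in uds if not u.empty) - 1,
                    }
                )
            summaries.append(s)
            retained += sum(len(p.trajectory) for p in parts)
        features = features_table(summaries)
        features.to_csv(out / "features.csv", index=False, float_format="%.8g")
        pd.DataFrame(fidelity_rows).to_csv(
            out / "fidelity.csv", index=False, float_format="%.8g"
        )
        counts["retained_points"] = retained
    except Exception as e:  # noqa: BLE001
        _write_manifest(out, config, counts, failed_stage="space_metrics")
        raise StageError("space_metrics", e) from e

    # --- screening ------------------------------------------------------
    try:
        report = screen_all(
            features, metadata, max_removals=config.max_outlier_removals
        )
        report.to_dataframe().to_csv(
            out / "screen.csv", index=False, float_format="%.8g"
        )
        (out / "screen.json").write_text(report.to_json())
        counts["screen_rows"] = len(report.fits)
    except Exception as e:  # noqa: BLE001
        _write_manifest(out, config, counts, failed_stage="model_screen")
        raise StageError("model_screen", e) from e

    # --- classification -------------------------------------------------
    ranking = None
    pool = candidate_features(report)
    counts["classifier_pool"] = len(pool)
    if pool:
        try:
            fits = select_logistic(
                features, metadata, pool, max_size=config.classifier_max_size
            )
            ranking = ranking_table(fits)
            ranking.to_csv(out / "classifier.csv", index=False, float_format="%.8g")
        except Exception as e:  # noqa: BLE001
            _write_manifest(out, config, counts, failed_stage="lameness_classifier")
            raise StageError("lameness_classifier", e) from e

    _write_manifest(out, config, counts)
    return {
        "features": features,
        "fidelity": pd.DataFrame(fidelity_rows),
        "screen": report,
        "classifier": ranking,
        "counts": counts,
        "out_dir": str(out),
    }


def _write_manifest(out: Path, config: RunConfig, counts: dict, failed_stage=None):
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.snapshot(),
        "counts": counts,
        "failed_stage": failed_stage,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
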