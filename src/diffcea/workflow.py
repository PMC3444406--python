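"""Config-driven end-to-end runs: scenario table, PSA, CEACs, manifest.

A run reproduces the full analysis layout — deterministic one-at-a-time
and combined scenarios over the trajectory years plus probabilistic
sensitivity analysis with acceptability curves per combined year — from
a single YAML config, writing CSV tables and a manifest (seed, package
version, config hash, per-file checksums) so the run is reconstructible
and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diffusion import (
    UPTAKE_MIXTURE,
    DiffusionDrivers,
    ScenarioTrajectory,
    default_trajectory,
    scenario_table,
)
from .economics import WTPThreshold
from .health_model import EconomicSettings, ModelValidationError
from .psa import PsaConfig, PsaResult, ceac, default_distributions, run_psa
from .synthetic_params import ParameterSet, generate_default

__all__ = ["AnalysisConfig", "run_full_analysis", "load_trajectory", "save_trajectory"]


def save_trajectory(trajectory: ScenarioTrajectory, path) -> None:
    data = {
        "points": [dataclasses.asdict(p) for p in trajectory.points],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_trajectory(path) -> ScenarioTrajectory:
    data = yaml.safe_load(Path(path).read_text())
    return ScenarioTrajectory(
        points=tuple(DiffusionDrivers(**p) for p in data["points"])
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Paths and settings for one full run (fail-fast validated)."""

    output_dir: str
    params_file: str | None = None  # None -> packaged synthetic default
    trajectory_file: str | None = None  # None -> packaged default trajectory
    settings: EconomicSettings = EconomicSettings()
    psa: PsaConfig = PsaConfig()
    threshold: WTPThreshold = WTPThreshold()
    uptake_mode: str = UPTAKE_MIXTURE
    psa_rel_se: float = 0.10
    verbosity: int = 1

    def __post_init__(self) -> None:
        for attr in ("params_file", "trajectory_file"):
            p = getattr(self, attr)
            if p is not None and not Path(p).is_file():
                raise ModelValidationError(f"{attr} {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        kwargs = dict(d)
        if "settings" in kwargs:
            kwargs["settings"] = EconomicSettings(**kwargs["settings"])
        if "psa" in kwargs:
            kwargs["psa"] = PsaConfig(**kwargs["psa"])
        if "threshold" in kwargs:
            kwargs["threshold"] = WTPThreshold(**kwargs["threshold"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "params_file": self.params_file,
                "trajectory_file": self.trajectory_file,
                "settings": dataclasses.asdict(self.settings),
                "psa": {
                    "n_iterations": self.psa.n_iterations,
                    "seed": self.psa.seed,
                    "lambda_grid": list(map(float, self.psa.lambda_grid)),
                },
                "threshold": dataclasses.asdict(self.threshold),
                "uptake_mode": self.uptake_mode,
                "psa_rel_se": self.psa_rel_se,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run scenario table + PSA + CEACs; returns the manifest dict.

    Any stage failure aborts with the stage name after removing the
    partial outputs of this run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    try:
        stage = "inputs"
        params = (
            ParameterSet.from_yaml(config.params_file)
            if config.params_file
            else generate_default()
        )
        params.validate()
        trajectory = (
            load_trajectory(config.trajectory_file)
            if config.trajectory_file
            else default_trajectory()
        )
        emit("params_used.yaml", lambda p: params.to_yaml(p))

        stage = "scenario-table"
        table = scenario_table(
            params,
            trajectory,
            config.settings,
            threshold=config.threshold,
            uptake_mode=config.uptake_mode,
        )
        emit("scenario_table.csv", lambda p: table.to_csv(p, index=False))

        stage = "psa"
        dists = default_distributions(params, rel_se=config.psa_rel_se)
        results: dict[str, PsaResult] = {}
        for point in trajectory:
            res = run_psa(
                params,
                point,
                dists,
                config.psa,
                config.settings,
                uptake_mode=config.uptake_mode,
                threshold=config.threshold,
            )
            results[point.year] = res
            emit(
                f"psa_draws_{point.year}.csv",
                lambda p, r=res: r.to_frame().to_csv(p, index=False),
            )

        stage = "ceac"
        for year, res in results.items():
            curve = ceac(res, config.psa.lambda_grid, label=year)
            emit(
                f"ceac_{year}.csv",
                lambda p, c=curve: c.to_frame().to_csv(p, index=False),
            )

        stage = "manifest"
        manifest = {
            "package": "diffcea",
            "version": __version__,
            "seed": config.psa.seed,
            "config_hash": config.config_hash(),
            "threshold": config.threshold.lambda_eur_per_qaly,
            "uptake_mode": config.uptake_mode,
            "files": {p.name: _sha256(p) for p in written},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc
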