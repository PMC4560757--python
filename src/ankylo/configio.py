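"""Configuration files, measurement I/O, seeding and run manifests.

Angles are degrees in human-facing config keys (``*_deg``) and radians in
data files.  Every randomized stage draws its seed deterministically from
the global seed and a stage label, so a run is replayable from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .elements import (
    COVALENT_RADII,
    DEFAULT_AMPLITUDES,
    ElementSpec,
    element_dictionary,
)
from .gespar import SolverConfig
from .scatter import EwaldSampling, Grid3D, MeasurementSet

__all__ = [
    "SimulationConfig",
    "RunConfig",
    "derive_seed",
    "load_config",
    "write_measurements",
    "read_measurements",
    "write_manifest",
]


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic stage seed < 2^31 from the global seed and a label."""
    return zlib.crc32(f"{label}:{global_seed}".encode()) & 0x7FFFFFFF


@dataclass
class SimulationConfig:
    """Simulation settings mirroring the JSON schema."""

    wavelength_angstrom: float = 0.35
    theta_min_deg: float = 2.0
    theta_max_deg: float = 160.0
    n_theta: int = 64
    n_phi: int = 64
    noise_level: float = 0.0
    seed: int = 0
    elements: list[dict] = field(default_factory=list)

    def sampling(self) -> EwaldSampling:
        return EwaldSampling.from_grid(
            self.wavelength_angstrom,
            theta_min=np.deg2rad(self.theta_min_deg),
            theta_max=np.deg2rad(self.theta_max_deg),
            n_theta=self.n_theta,
            n_phi=self.n_phi,
        )

    def element_dictionary(self) -> list[ElementSpec]:
        if not self.elements:
            raise ValueError("config.elements is empty")
        counts = {e["symbol"]: int(e["count"]) for e in self.elements}
        radii = {
            e["symbol"]: float(e["radius_angstrom"])
            for e in self.elements
            if "radius_angstrom" in e
        }
        amps = {
            e["symbol"]: float(e["amplitude"]) for e in self.elements if "amplitude" in e
        }
        return element_dictionary(counts, radii=radii, amplitudes=amps)

    def radii_overrides(self) -> dict[str, float]:
        return {
            e["symbol"]: float(e["radius_angstrom"])
            for e in self.elements
            if "radius_angstrom" in e
        }

    def amplitude_overrides(self) -> dict[str, float]:
        return {e["symbol"]: float(e["amplitude"]) for e in self.elements if "amplitude" in e}


@dataclass
class RunConfig:
    """Merged simulation + grid + solver configuration with provenance."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grid_n: int = 41
    grid_spacing_angstrom: float = 0.2
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0
    source_path: str | None = None

    def grid(self, center: np.ndarray | None = None) -> Grid3D:
        return Grid3D.centered(
            extent=(self.grid_n - 1) * self.grid_spacing_angstrom,
            n=self.grid_n,
            center=center,
        )

    def stage_seed(self, label: str) -> int:
        return derive_seed(self.seed, label)


_SIM_KEYS = {f.strip() for f in (
    "wavelength_angstrom theta_min_deg theta_max_deg n_theta n_phi noise_level seed elements"
).split()}
_SOLVER_KEYS = set(SolverConfig.__dataclass_fields__)
_TOP_KEYS = {"grid_n", "grid_spacing_angstrom", "seed", "simulation", "solver"} | _SIM_KEYS


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load a JSON config; simulation keys may be flat or nested.

    Schema violations are reported with the offending key path.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a JSON object")
    for k in raw:
        if k not in _TOP_KEYS:
            raise ValueError(f"{path}: unknown config key {k!r}")
    sim_raw = dict(raw.get("simulation", {}))
    for k in list(raw):
        if k in _SIM_KEYS:
            sim_raw[k] = raw[k]
    for k in sim_raw:
        if k not in _SIM_KEYS:
            raise ValueError(f"{path}: simulation.{k}: unknown key")
    solver_raw = dict(raw.get("solver", {}))
    for k in solver_raw:
        if k not in _SOLVER_KEYS:
            raise ValueError(f"{path}: solver.{k}: unknown key")
    try:
        sim = SimulationConfig(**sim_raw)
        solver = SolverConfig(**solver_raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
    cfg = RunConfig(
        simulation=sim,
        grid_n=int(raw.get("grid_n", 41)),
        grid_spacing_angstrom=float(raw.get("grid_spacing_angstrom", 0.2)),
        solver=solver,
        seed=int(raw.get("seed", sim.seed)),
        source_path=str(path),
    )
    if seed_override is not None:
        cfg.seed = int(seed_override)
    return cfg


# ---------------------------------------------------------------------------
# measurement files: CSV + JSON sidecar


def write_measurements(measurements: MeasurementSet, csv_path: str | Path) -> Path:
    """Write intensities as CSV (theta_rad,phi_rad,intensity) plus a JSON
    sidecar (same stem, .json) with wavelength, mask, noise and power."""
    csv_path = Path(csv_path)
    s = measurements.sampling
    df = pd.DataFrame(
        {"theta_rad": s.theta, "phi_rad": s.phi, "intensity": measurements.intensities}
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "wavelength_angstrom": s.wavelength,
        "theta_min_rad": s.theta_min,
        "theta_max_rad": s.theta_max,
        "noise_level": measurements.noise_level,
        "seed": measurements.seed,
        "total_signal_power": measurements.total_signal_power,
        "n_measurements": len(measurements),
    }
    side_path = csv_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return side_path


def read_measurements(csv_path: str | Path) -> MeasurementSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("theta_rad", "phi_rad", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{csv_path}: missing column {col!r}")
    side = json.loads(csv_path.with_suffix(".json").read_text())
    sampling = EwaldSampling(
        wavelength=float(side["wavelength_angstrom"]),
        theta=df["theta_rad"].to_numpy(),
        phi=df["phi_rad"].to_numpy(),
        theta_min=float(side["theta_min_rad"]),
        theta_max=float(side["theta_max_rad"]),
    )
    return MeasurementSet(
        intensities=df["intensity"].to_numpy(),
        sampling=sampling,
        noise_level=float(side.get("noise_level", 0.0)),
        seed=side.get("seed"),
        total_signal_power=float(side.get("total_signal_power", 0.0)),
    )


def write_manifest(out_dir: str | Path, config: RunConfig, stage: str, **extra: Any) -> Path:
    """Machine-readable run manifest: config hash, seeds, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": config.seed,
        "config": {
            "simulation": asdict(config.simulation),
            "grid_n": config.grid_n,
            "grid_spacing_angstrom": config.grid_spacing_angstrom,
            "solver": asdict(config.solver),
        },
        "version": __version__,
        **extra,
    }
    blob = json.dumps(payload, sort_keys=True)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
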