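"""Run configuration: YAML-configurable parameter blocks with validation.

A run config bundles the paradigm specification and every parameter block of
the pipeline (transfer-function coefficients, canal basis, fusion gains,
observer gains, population model).  Defaults are the package's trained /
calibrated values; any block may be overridden from YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .afferent import DEFAULT_TF_COEFFICIENTS, TransferFunctionSpec, default_tf_bank
from .fusion import FusionParams
from .geometry import CanalBasis, default_canal_basis
from .observer import ObserverParams
from .population import PopulationModel

__all__ = ["RunConfig", "load_config", "resolved_config_dict"]


@dataclass
class RunConfig:
    """Validated parameter bundle for a simulation / fit / Monte Carlo run."""

    paradigm: dict = field(default_factory=dict)
    tf_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_TF_COEFFICIENTS))
    fusion: FusionParams = field(default_factory=FusionParams)
    observer: ObserverParams = field(default_factory=ObserverParams)
    population: PopulationModel = field(default_factory=PopulationModel)
    basis_alignment_deg: float = 7.0
    canal_normals_right: list | None = None  # 3x3 rows A/P/H; mirrored for the left ear
    seed: int = 0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("config.dt: must be positive")
        if not isinstance(self.seed, int):
            raise ValueError("config.seed: must be an integer")

    def tf_bank(self) -> dict[tuple[str, str], TransferFunctionSpec]:
        return default_tf_bank(self.tf_coefficients)

    def canal_basis(self) -> CanalBasis:
        if self.canal_normals_right is None:
            return default_canal_basis(self.basis_alignment_deg)
        n_right = np.asarray(self.canal_normals_right, dtype=float)
        if n_right.shape != (3, 3):
            raise ValueError("canal_normals_right: expected 3 rows of 3 numbers (A/P/H)")
        n_right = n_right / np.linalg.norm(n_right, axis=1, keepdims=True)
        mirror = np.diag([-1.0, 1.0, -1.0])
        return CanalBasis(
            n_right=n_right, n_left=n_right @ mirror.T, alignment_deg=self.basis_alignment_deg
        )


def _parse_tf_block(block: dict) -> dict:
    out = dict(DEFAULT_TF_COEFFICIENTS)
    for key, val in block.items():
        try:
            channel, polarity = key.split("/")
        except ValueError as err:
            raise ValueError(
                f"tf_coefficients.{key}: keys must be 'channel/polarity' (e.g. 'irregular/cathodal')"
            ) from err
        for f in ("zeros", "poles", "gain"):
            if f not in val:
                raise ValueError(f"tf_coefficients.{key}.{f}: missing")
        out[(channel, polarity)] = {"zeros": val["zeros"], "poles": val["poles"], "gain": val["gain"]}
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from optional YAML plus programmatic overrides.

    Schema errors are reported with their field path.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        data.update(overrides)

    kwargs: dict = {}
    for scalar in ("seed", "dt", "basis_alignment_deg", "canal_normals_right"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if "paradigm" in data:
        kwargs["paradigm"] = data.pop("paradigm")
    if "tf_coefficients" in data:
        kwargs["tf_coefficients"] = _parse_tf_block(data.pop("tf_coefficients"))
    for name, cls in (("fusion", FusionParams), ("observer", ObserverParams), ("population", PopulationModel)):
        if name in data:
            block = data.pop(name)
            valid = {f for f in cls.__dataclass_fields__}
            unknown = set(block) - valid
            if unknown:
                raise ValueError(f"{name}.{sorted(unknown)[0]}: unknown field")
            try:
                kwargs[name] = cls(**block)
            except (TypeError, ValueError) as err:
                raise ValueError(f"{name}: {err}") from err
    if data:
        raise ValueError(f"unknown top-level config field {sorted(data)[0]!r}")
    return RunConfig(**kwargs)


def resolved_config_dict(config: RunConfig) -> dict:
    """Fully resolved config as plain JSON-serializable data (for provenance)."""
    d = {
        "paradigm": config.paradigm,
        "fusion": asdict(config.fusion),
        "observer": asdict(config.observer),
        "population": asdict(config.population),
        "basis_alignment_deg": config.basis_alignment_deg,
        "canal_normals_right": config.canal_normals_right,
        "seed": config.seed,
        "dt": config.dt,
        "tf_coefficients": {
            f"{ch}/{pol}": {k: (list(v) if isinstance(v, (list, tuple)) else v) for k, v in c.items()}
            for (ch, pol), c in config.tf_coefficients.items()
        },
    }
    return d
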