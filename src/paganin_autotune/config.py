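"""Run configuration for the end-to-end pipeline, loadable from YAML."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

PLANCK_HC_EV_M = 1.23984193e-6  # h*c in eV*m, for keV -> wavelength


class GeometryConfig(BaseModel):
    """Experimental geometry; energy_kev is converted to wavelength on load."""

    pixel_size: float = Field(gt=0, default=1.0)
    z: Optional[float] = Field(default=None, gt=0)
    wavelength: Optional[float] = Field(default=None, gt=0)
    energy_kev: Optional[float] = Field(default=None, gt=0)
    mu: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _energy_to_wavelength(self) -> "GeometryConfig":
        if self.wavelength is None and self.energy_kev is not None:
            object.__setattr__(self, "wavelength",
                               PLANCK_HC_EV_M / (self.energy_kev * 1e3))
        return self


class SelectorConfig(BaseModel):
    eps: float = Field(default=0.01, gt=0, lt=1)
    r_hat: float = Field(default=0.5, gt=0, lt=1)
    delta_r: float = Field(default=0.1, ge=0)
    n_rings: Optional[int] = Field(default=None, ge=2)
    split_scheme: str = "rows"
    grid_min: float = Field(default=1e-2, gt=0)
    grid_max: float = Field(default=1e8, gt=0)
    grid_points: int = Field(default=128, ge=8)
    grid_subintervals: int = Field(default=8, ge=1)
    bounds_min: float = Field(default=0.0, ge=0)
    bounds_max: float = Field(default=1e8, gt=0)


class RunConfig(BaseModel):
    """Paths, geometry, selector settings, seed and log level for one run."""

    frame: str
    flat: str
    output_dir: str = "."
    frame_dataset: str = "data"
    geometry: GeometryConfig = GeometryConfig()
    selector: SelectorConfig = SelectorConfig()
    contrast_block: int = Field(default=32, ge=2)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def content_hash(self) -> str:
        """Stable hash of the configuration, for report provenance."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def resolve(self, base: Path | None = None) -> "RunConfig":
        if base is None:
            return self
        upd = self.model_copy()
        for name in ("frame", "flat", "output_dir"):
            p = Path(getattr(self, name))
            if not p.is_absolute():
                setattr(upd, name, str(base / p))
        return upd
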