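"""Configuration-file handling for the command-line interface.

A config file (YAML; JSON is a YAML subset) supplies either a
``dimensional:`` block with the eight rate/affinity constants, a
``dimensionless:`` block with eta1..eta4, or both. When both are present
they must be mutually consistent to 1e-9 relative, and the dimensional
block also yields the concentration/time scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .params import (
    DimensionalParams,
    DimensionlessParams,
    Scales,
    ValidationError,
    nondimensionalise,
)

__all__ = ["ModelConfig", "load_config"]

_DIM_KEYS = ("k1", "k2", "k3", "k4", "k5", "P0", "X0", "alpha")
_ETA_KEYS = ("eta1", "eta2", "eta3", "eta4")
_CONSISTENCY_RTOL = 1e-9


@dataclass(frozen=True)
class ModelConfig:
    dimensionless: DimensionlessParams
    dimensional: DimensionalParams | None
    scales: Scales | None
    source: str

    def as_dict(self) -> dict:
        out: dict = {"dimensionless": vars(self.dimensionless).copy()}
        if self.dimensional is not None:
            out["dimensional"] = vars(self.dimensional).copy()
        if self.scales is not None:
            out["scales"] = vars(self.scales).copy()
        return out


def _block(raw: dict, name: str, keys) -> dict:
    block = raw[name]
    if not isinstance(block, dict):
        raise ValidationError(f"config block {name!r} must be a mapping")
    missing = [k for k in keys if k not in block]
    extra = [k for k in block if k not in keys]
    if missing:
        raise ValidationError(f"config block {name!r} is missing keys {missing}")
    if extra:
        raise ValidationError(f"config block {name!r} has unknown keys {extra}")
    return {k: float(block[k]) for k in keys}


def load_config(path) -> ModelConfig:
    """Read and validate a parameter config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping at top level")
    has_dim = "dimensional" in raw
    has_eta = "dimensionless" in raw
    if not (has_dim or has_eta):
        raise ValidationError(
            "config must contain a 'dimensional' and/or 'dimensionless' block"
        )

    dim = scales = None
    if has_dim:
        dim = DimensionalParams(**_block(raw, "dimensional", _DIM_KEYS))
        mapped, scales = nondimensionalise(dim)
    if has_eta:
        etas = DimensionlessParams(**_block(raw, "dimensionless", _ETA_KEYS))
        if has_dim:
            for key in _ETA_KEYS:
                a, b = getattr(etas, key), getattr(mapped, key)
                if abs(a - b) > _CONSISTENCY_RTOL * max(abs(a), abs(b)):
                    raise ValidationError(
                        f"dimensional and dimensionless blocks disagree on {key}: "
                        f"{b!r} (mapped) vs {a!r} (stated)"
                    )
    else:
        etas = mapped
    source = "both" if (has_dim and has_eta) else ("dimensional" if has_dim else "dimensionless")
    return ModelConfig(dimensionless=etas, dimensional=dim, scales=scales, source=source)
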