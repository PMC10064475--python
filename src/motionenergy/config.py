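"""Run configuration: a flat, human-readable key-value schema.

One ``RunConfig`` validates and carries everything a pipeline run needs —
filter-bank parameters, the normalisation switch, color-wheel settings and
the random seed. Configs load from flat YAML mappings (no nesting; unknown
keys are an error so typos fail fast) and CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .decode import ColorWheelConfig
from .filterbank import DEFAULTS, FilterBank, build_filterbank
from .stimuli import ParameterError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for an end-to-end run.

    Field names are the config-file keys. ``wavelength_px`` may be a single
    number or a comma-separated list for a multi-scale bank.
    """

    K: int = DEFAULTS["K"]
    wavelength_px: float | tuple[float, ...] = DEFAULTS["wavelength_px"]
    sigma_px: float = DEFAULTS["sigma_px"]
    tau_frames: float = DEFAULTS["tau_frames"]
    kernel_size: int = DEFAULTS["kernel_size"]
    n_taps: int = DEFAULTS["n_taps"]
    normalize: bool = False
    hue_at_zero_deg: float = 0.0
    direction_of_increase: str = "cw"
    magnitude_percentile: float = 99.0
    gamma: float = 1.0
    fixed_scale: float | None = None
    seed: int = 0

    def __post_init__(self):
        # constructing the dependents validates every module precondition
        self.to_colorwheel()
        if self.K < 4 or self.K % 2:
            raise ParameterError("K must be even and >= 4")
        if self.seed < 0:
            raise ParameterError("seed must be >= 0")

    def to_bank(self) -> FilterBank:
        return build_filterbank(
            K=self.K,
            wavelength_px=self.wavelength_px,
            sigma_px=self.sigma_px,
            tau_frames=self.tau_frames,
            kernel_size=self.kernel_size,
            n_taps=self.n_taps,
        )

    def to_colorwheel(self) -> ColorWheelConfig:
        return ColorWheelConfig(
            hue_at_zero_deg=self.hue_at_zero_deg,
            direction_of_increase=self.direction_of_increase,  # type: ignore[arg-type]
            magnitude_percentile=self.magnitude_percentile,
            gamma=self.gamma,
            fixed_scale=self.fixed_scale,
        )

    @classmethod
    def from_mapping(cls, mapping: dict, **overrides) -> "RunConfig":
        """Build from a flat mapping; ``overrides`` win over ``mapping``."""
        known = {f.name for f in dataclasses.fields(cls)}
        merged = {**mapping, **{k: v for k, v in overrides.items() if v is not None}}
        unknown = set(merged) - known
        if unknown:
            raise ParameterError(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        if "wavelength_px" in merged and isinstance(merged["wavelength_px"], str):
            parts = [float(p) for p in merged["wavelength_px"].split(",")]
            merged["wavelength_px"] = parts[0] if len(parts) == 1 else tuple(parts)
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a flat YAML key-value file (empty file = all defaults)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"config file {path} must be a flat key-value mapping")
        return cls.from_mapping(raw, **overrides)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if isinstance(d["wavelength_px"], tuple):
            d["wavelength_px"] = ",".join(str(w) for w in d["wavelength_px"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
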