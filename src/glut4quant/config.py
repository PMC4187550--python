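"""Pipeline configuration: defaults, YAML loading, validation, provenance.

The defaults encode the analysis constants of the method: a plasma-membrane
(PM) band of half-width 2.5 px about the dystrophin midline (total thickness
5 px), twenty concentric 1 μm intracellular layers, and a 1 μm equivalent-
diameter boundary between "large" and "small" GLUT4 spots.  Spot detection
thresholds are uniform study-level constants, not per-image values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigValidationError

log = logging.getLogger("glut4quant")


@dataclass
class SnakeParams:
    """Active-contour (snake) parameters.

    alpha: tension (first-derivative) weight; beta: rigidity (second
    derivative); sigma_px: Gaussian scale of the external-energy image;
    line_weight/edge_weight: weights of the ridge (smoothed intensity) and
    edge (squared gradient magnitude) terms of the external energy;
    step: time step of the semi-implicit update; tol_px: stop when the
    maximum vertex displacement in one iteration falls below this;
    max_iter: iteration cap.
    """

    alpha: float = 0.05
    beta: float = 2.0
    sigma_px: float = 2.0
    line_weight: float = 1.0
    edge_weight: float = 0.0
    ext_weight: float = 2.0
    step: float = 1.0
    tol_px: float = 0.05
    max_iter: int = 2000


@dataclass
class PreprocessParams:
    """GLUT4 detection-channel preprocessing.

    Stage 1 emulates a no-neighbour deconvolution as clipped subtraction of
    a wide Gaussian background estimate; stage 2 is a high-pass Gaussian
    ("HiGauss") enhancement.  The filtered channel is used only for spot
    detection, never for intensity measurements.
    """

    background_sigma_px: float = 10.0
    background_weight: float = 1.0
    highpass_sigma_px: float = 2.0
    highpass_gain: float = 2.0


@dataclass
class PipelineConfig:
    band_halfwidth_px: float = 2.5
    n_layers: int = 20
    layer_thickness_um: float = 1.0
    spot_intensity_threshold: float = 45.0
    spot_min_area_px: int = 4
    size_class_boundary_um: float = 1.0
    snake: SnakeParams = field(default_factory=SnakeParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    provenance: dict = field(default_factory=dict, compare=False)

    def resolved(self) -> dict:
        """Flat mapping of every key to (value, provenance)."""
        out = {}
        for f in dataclasses.fields(self):
            if f.name == "provenance":
                continue
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                for g in dataclasses.fields(v):
                    key = f"{f.name}.{g.name}"
                    out[key] = (getattr(v, g.name), self.provenance.get(key, "default"))
            else:
                out[f.name] = (v, self.provenance.get(f.name, "default"))
        return out

    def log_resolved(self):
        for key, (value, prov) in self.resolved().items():
            log.info("config %-32s = %-10r (%s)", key, value, prov)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return the list of violations (empty when the config is valid)."""
    v = []
    if cfg.band_halfwidth_px <= 0:
        v.append(f"band_halfwidth_px must be > 0, got {cfg.band_halfwidth_px}")
    if cfg.n_layers < 1:
        v.append(f"n_layers must be >= 1, got {cfg.n_layers}")
    if cfg.layer_thickness_um <= 0:
        v.append(f"layer_thickness_um must be > 0, got {cfg.layer_thickness_um}")
    if cfg.spot_intensity_threshold < 0:
        v.append(f"spot_intensity_threshold must be >= 0, got {cfg.spot_intensity_threshold}")
    if cfg.spot_min_area_px < 0:
        v.append(f"spot_min_area_px must be >= 0, got {cfg.spot_min_area_px}")
    if cfg.size_class_boundary_um <= 0:
        v.append(f"size_class_boundary_um must be > 0, got {cfg.size_class_boundary_um}")
    if cfg.snake.max_iter < 1:
        v.append("snake.max_iter must be >= 1")
    if cfg.snake.tol_px <= 0:
        v.append("snake.tol_px must be > 0")
    for name in ("background_sigma_px", "highpass_sigma_px"):
        if getattr(cfg.preprocess, name) <= 0:
            v.append(f"preprocess.{name} must be > 0")
    return v


def _apply(cfg: PipelineConfig, data: dict, prefix: str = ""):
    for key, val in data.items():
        if not hasattr(cfg, key):
            raise ConfigValidationError([f"unknown config key {prefix + key!r}"])
        current = getattr(cfg, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(val, dict):
                raise ConfigValidationError([f"{prefix + key!r} must be a mapping"])
            _apply(current, val, prefix=f"{key}.")
            for sub in val:
                cfg.provenance if prefix else None
        else:
            setattr(cfg, key, type(current)(val) if current is not None else val)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config file; unspecified keys take the documented defaults.

    ``overrides`` (e.g. from CLI flags) take precedence over the file, which
    takes precedence over defaults; provenance per key is recorded as
    ``default``, ``file`` or ``user``.
    """
    cfg = PipelineConfig()

    def mark(data, source, prefix=""):
        for key, val in (data or {}).items():
            if isinstance(val, dict) and hasattr(cfg, key) and dataclasses.is_dataclass(getattr(cfg, key)):
                for sub in val:
                    cfg.provenance[f"{key}.{sub}"] = source
            else:
                cfg.provenance[key] = source

    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigValidationError([f"config file {path} is not a mapping"])
        _apply(cfg, data)
        mark(data, "file")
    if overrides:
        _apply(cfg, overrides)
        mark(overrides, "user")
    violations = validate_config(cfg)
    if violations:
        raise ConfigValidationError(violations)
    return cfg
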