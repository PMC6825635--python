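"""Pipeline configuration.

A :class:`PipelineConfig` gathers everything a full run needs: input
location and voxel spacing, the isotropic analysis grid (5 µm default),
segmentation settings (automatic histogram-derived thresholds or fixed
values), the vessel-calibre class bounds (3 and 11 µm defaults) and the
output location.  Configs round-trip through YAML for reproducible runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ParameterError

__all__ = ["SegmentationConfig", "PipelineConfig", "load_config", "save_config"]


@dataclass
class SegmentationConfig:
    """``mode: auto`` derives thresholds from the intensity histogram;
    ``mode: fixed`` uses the given low/high values (raw intensity units)."""

    mode: str = "auto"
    low: float | None = None
    high: float | None = None
    connectivity: int = 26
    min_component_voxels: int = 27

    def __post_init__(self):
        if self.mode not in ("auto", "fixed"):
            raise ParameterError(f"segmentation mode must be auto|fixed, got {self.mode!r}")
        if self.mode == "fixed":
            if self.low is None or self.high is None:
                raise ParameterError("fixed mode requires low and high thresholds")
            if not (0 <= self.low <= self.high):
                raise ParameterError("need 0 <= low <= high")


@dataclass
class PipelineConfig:
    input_path: str = ""
    spacing_um: tuple[float, float, float] = (5.0, 0.585, 0.585)
    target_grid_um: float = 5.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tissue_mask_path: str | None = None
    radius_thin_below_um: float = 3.0
    radius_thick_above_um: float = 11.0
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationConfig(**self.segmentation)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ParameterError("spacing_um must be three positive values")
        if self.target_grid_um <= 0:
            raise ParameterError("target_grid_um must be positive")
        if not (0 < self.radius_thin_below_um < self.radius_thick_above_um):
            raise ParameterError("need 0 < thin bound < thick bound")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str) -> str:
    data = asdict(config)
    data["spacing_um"] = list(config.spacing_um)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
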