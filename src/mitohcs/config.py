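"""Analysis configuration with documented package defaults.

All thresholds are expressed on the [0, 1] intensity scale.  Sizes are in
pixels at the acquisition resolution; ``pixel_size_um`` converts lengths
to micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .segmentation import ThresholdSpec

__all__ = ["H2O2Params", "MmpParams", "MorphologyParams", "AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class H2O2Params:
    feature_size: float = 35.0                 # top-hat scale = upper puncta diameter
    puncta_diameter: tuple[float, float] = (3.0, 35.0)
    denominator: str = "mito"                  # or "puncta"


@dataclass(frozen=True)
class MmpParams:
    aggregate_diameter: tuple[float, float] = (3.0, 15.0)
    monomer_mask_mode: str = "aggregate_footprint"  # or "complement"


@dataclass(frozen=True)
class MorphologyParams:
    tubeness_sigma: float = 1.5
    manual_floor: float = 0.1
    mito_diameter: tuple[float, float] = (3.0, 100.0)
    # mitochondrial tubes are only ~3 px wide at this magnification, so no
    # subsampling by default; lower (e.g. 0.25) trades resolution for speed
    granularity_subsample: float = 1.0
    granularity_element_size: int = 10
    granularity_length: int = 16
    fragmentation_scales: int = 3              # k: spectrum bins summed into the headline %
    # spectrum input: the binary mitochondrial object image ("binary"),
    # the raw stain ("raw") or the tubeness response ("enhanced")
    granularity_source: str = "binary"


@dataclass(frozen=True)
class AnalysisConfig:
    channel_map: Mapping[int, str] = field(
        default_factory=lambda: {1: "hoechst", 2: "mitoid_red", 3: "mitopy1",
                                 4: "jc10_orange", 5: "jc10_green"}
    )
    pixel_size_um: float = 0.299
    illumination_correction: bool = True
    # nuclei: global three-class Otsu, middle class to background (dim debris)
    nucleus_spec: ThresholdSpec = ThresholdSpec(method="otsu3", middle_class="background")
    nucleus_diameter: tuple[float, float] = (10.0, 80.0)
    # cell body: three-class Otsu keeping the dim cytoplasmic haze as foreground
    cell_spec: ThresholdSpec = ThresholdSpec(method="otsu3", middle_class="foreground")
    propagation_regularization: float = 0.05
    nucleus_area: tuple[float, float] = (100.0, 10_000.0)
    max_eccentricity: float = 0.95
    drop_border_cells: bool = True
    # mitochondrial mask for the colocalization denominator: bright class only
    mito_mask_spec: ThresholdSpec = ThresholdSpec(method="otsu3", middle_class="background")
    h2o2: H2O2Params = H2O2Params()
    mmp: MmpParams = MmpParams()
    morphology: MorphologyParams = MorphologyParams()


def _threshold_spec(d: Mapping) -> ThresholdSpec:
    d = dict(d)
    if "bounds" in d:
        d["bounds"] = tuple(d["bounds"])
    return ThresholdSpec(**d)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; absent keys keep package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("pixel_size_um", "illumination_correction", "propagation_regularization",
                "max_eccentricity", "drop_border_cells"):
        if key in raw:
            kwargs[key] = raw[key]
    if "channel_map" in raw:
        kwargs["channel_map"] = {int(k): str(v) for k, v in raw["channel_map"].items()}
    for key in ("nucleus_diameter", "nucleus_area"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("nucleus_spec", "cell_spec", "mito_mask_spec"):
        if key in raw:
            kwargs[key] = _threshold_spec(raw[key])
    for key, cls in (("h2o2", H2O2Params), ("mmp", MmpParams), ("morphology", MorphologyParams)):
        if key in raw:
            sub = dict(raw[key])
            for tup_key in ("puncta_diameter", "aggregate_diameter", "mito_diameter"):
                if tup_key in sub:
                    sub[tup_key] = tuple(sub[tup_key])
            kwargs[key] = cls(**sub)
    return AnalysisConfig(**kwargs)


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config back to YAML (for run logs and reproducibility)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_listify(asdict(config)), fh, sort_keys=False)
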