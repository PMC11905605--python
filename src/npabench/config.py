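"""Configuration objects for the simulator, both segmenters and the study runner.

Every tunable lives in one of these dataclasses so that a sensitivity sweep is
a loop over configs, not a code change.  All configs round-trip losslessly
through YAML/JSON dictionaries via :func:`to_dict` / :func:`from_dict`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .types import (
    ETDRS_LEVELS,
    NONREFERABLE,
    REFERABLE,
    SEVERITY_GROUPS,
    VISION_THREATENING,
)


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


# ---------------------------------------------------------------------------
# cohort / simulator
# ---------------------------------------------------------------------------

def _default_severity_weights() -> dict[int, float]:
    # First-visit severity mix: 22% nonreferable, 55% referable but
    # non-vision-threatening, 23% vision-threatening; split within groups
    # with most mass at the low referable levels.
    w = {
        10: 0.12, 20: 0.10,
        35: 0.22, 43: 0.20, 47: 0.13,
        53: 0.08, 61: 0.05, 65: 0.04, 71: 0.03, 75: 0.015, 81: 0.01, 85: 0.005,
    }
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def _default_ssi_model() -> dict[str, dict[str, float]]:
    # Scan quality declines with severity: the nonreferable-vs-referable SSI
    # gap defaults to ~8 points, matching the confound the analysis must
    # handle.  Set the means equal for confound-free experiments.
    return {
        NONREFERABLE: {"mean": 72.0, "sd": 6.0},
        REFERABLE: {"mean": 63.6, "sd": 7.0},
        VISION_THREATENING: {"mean": 63.2, "sd": 7.0},
    }


def _default_lesion_model() -> dict[str, dict[str, float]]:
    # Expected total extrafoveal capillary-dropout area (mm^2) per severity
    # group and the mean lesion count.  ETDRS level 10 always plants zero
    # lesions regardless of the nonreferable entry.
    return {
        NONREFERABLE: {"mean_area_mm2": 0.30, "mean_count": 1.5},
        REFERABLE: {"mean_area_mm2": 1.40, "mean_count": 4.0},
        VISION_THREATENING: {"mean_area_mm2": 1.90, "mean_count": 5.0},
    }


def _default_noise_model() -> dict[str, float]:
    # Additive clipped-Gaussian decorrelation noise, sd = a + b * (100 - SSI).
    return {"a": 0.02, "b": 0.003}


def _default_shadow_model() -> dict[str, float]:
    # Vitreous-floater / pupil-vignetting style shadows: per-visit probability
    # of carrying any shadow, disk radius range (px), and the multiplicative
    # attenuation applied to BOTH channels inside the disk.  Media opacities
    # both cast shadows and lower the signal strength index, so the effective
    # probability rises as SSI falls: prob * (1 + ssi_link * (70 - SSI)).
    return {
        "prob": 0.35,
        "max_disks": 2,
        "radius_lo_px": 12.0,
        "radius_hi_px": 28.0,
        "attenuation_lo": 0.25,
        "attenuation_hi": 0.5,
        "ssi_link": 0.03,
    }


def _default_slab_params() -> dict[str, dict[str, float]]:
    # Per-plexus vessel geometry: target intercapillary spacing (max distance
    # from any perfused point to the nearest vessel, px) and vessel caliber
    # (dilation radius of the centerline, px).  The SVC is coarser, the
    # ICP/DCP finer; deeper slabs get a noise multiplier (more decorrelation
    # background at depth).
    return {
        "SVC": {"spacing_px": 7.0, "caliber_px": 1.0, "noise_factor": 1.0},
        "ICP": {"spacing_px": 5.5, "caliber_px": 0.5, "noise_factor": 1.15},
        "DCP": {"spacing_px": 5.5, "caliber_px": 0.5, "noise_factor": 1.3},
        "INNER": {"spacing_px": 0.0, "caliber_px": 0.0, "noise_factor": 1.0},
    }


@dataclass
class CohortConfig:
    """Design of one synthetic cohort.

    The factorial design is participants x eyes_per_participant x
    visits_per_eye x 4 slabs.  Severity is an eye-level property held constant
    across visits; SSI, noise and shadows vary per visit.
    """

    n_participants: int = 40
    eyes_per_participant: int = 2
    visits_per_eye: int = 1
    severity_weights: dict[int, float] = field(default_factory=_default_severity_weights)
    ssi_model: dict[str, dict[str, float]] = field(default_factory=_default_ssi_model)
    lesion_model: dict[str, dict[str, float]] = field(default_factory=_default_lesion_model)
    noise_model: dict[str, float] = field(default_factory=_default_noise_model)
    shadow_model: dict[str, float] = field(default_factory=_default_shadow_model)
    slab_params: dict[str, dict[str, float]] = field(default_factory=_default_slab_params)
    fovea_radius_mean_px: float = 30.0
    fovea_radius_sd_px: float = 4.0
    ssi_floor: float = 30.0
    seed: int = 0
    id_prefix: str = "P"

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if self.eyes_per_participant not in (1, 2):
            raise ConfigError("eyes_per_participant must be 1 or 2")
        if not 1 <= self.visits_per_eye <= 3:
            raise ConfigError("visits_per_eye must be in 1..3")
        if not self.severity_weights:
            raise ConfigError("severity_weights must be nonempty")
        for level in self.severity_weights:
            if level not in ETDRS_LEVELS:
                raise ConfigError(f"severity_weights: unsupported ETDRS level {level}")
        total = sum(self.severity_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"severity_weights must sum to 1, got {total}")
        if any(w < 0 for w in self.severity_weights.values()):
            raise ConfigError("severity_weights must be nonnegative")
        from .types import severity_group as _group

        needed = {
            _group(level)
            for level, w in self.severity_weights.items()
            if w > 0 and level != 10
        }
        needed_ssi = {_group(level) for level, w in self.severity_weights.items() if w > 0}
        for group in needed_ssi:
            if group not in self.ssi_model:
                raise ConfigError(f"ssi_model missing severity group {group!r}")
            if not 0.0 <= self.ssi_model[group]["mean"] <= 100.0:
                raise ConfigError(f"ssi_model[{group!r}] mean must lie in [0, 100]")
        for group in needed:
            if group not in self.lesion_model:
                raise ConfigError(f"lesion_model missing severity group {group!r}")
        if self.noise_model["a"] < 0 or self.noise_model["b"] < 0:
            raise ConfigError("noise_model coefficients must be nonnegative")
        if self.fovea_radius_mean_px < 0:
            raise ConfigError("fovea_radius_mean_px must be nonnegative")


# ---------------------------------------------------------------------------
# rules-based segmenter
# ---------------------------------------------------------------------------

@dataclass
class RBParams:
    """Tunables of the rules-based NPA segmenter.

    ``distance_threshold_px`` is normally not set by hand: it is calibrated on
    healthy eyes so that the full pipeline finds no NPA outside the fovea
    (see :func:`npabench.rb.calibrate_distance_threshold`).
    """

    vesselness_scales_px: tuple[float, ...] = (1.0, 2.0, 3.0)
    vesselness_beta: float = 0.5
    # response scale: noise ridges (S ~ 0.05) score near zero, shadow-
    # attenuated vessels (S ~ 0.15-0.25) score midrange, full-signal vessels
    # (S ~ 0.5-1) saturate
    vesselness_c: float = 0.15
    binarize_window_px: int = 31
    # negative offset raises the local threshold by a fixed amount, acting as
    # a noise floor that rejects spurious vesselness in avascular regions
    binarize_offset: float = -0.12
    reflectance_compensation_strength: float = 0.6
    distance_threshold_px: float = 8.0
    min_region_area_mm2: float = 0.03
    morphology_radius_px: int = 1
    calibration_grid_px: tuple[float, float, float] = (1.0, 40.0, 0.5)
    fovea_dilation_px: int = 10

    def validate(self) -> None:
        scales = tuple(self.vesselness_scales_px)
        if not scales or any(s <= 0 for s in scales):
            raise ConfigError("vesselness_scales_px must be positive")
        if list(scales) != sorted(scales):
            raise ConfigError("vesselness_scales_px must be sorted ascending")
        if self.binarize_window_px < 3 or self.binarize_window_px % 2 == 0:
            raise ConfigError("binarize_window_px must be odd and >= 3")
        if self.distance_threshold_px <= 0:
            raise ConfigError("distance_threshold_px must be > 0")
        if self.min_region_area_mm2 < 0:
            raise ConfigError("min_region_area_mm2 must be >= 0")


# ---------------------------------------------------------------------------
# learned segmenter
# ---------------------------------------------------------------------------

@dataclass
class SegmenterConfig:
    """Hyperparameters of the learned NPA segmenter.

    The model is a fully convolutional pixel classifier: a fixed multiscale
    Gaussian-pyramid encoder turns the 2-channel (angio, structure) image into
    per-pixel hypercolumn features, and a small MLP head learns the mapping to
    NPA probability.  ``feature_scales_px`` are the Gaussian smoothing sigmas.
    """

    feature_scales_px: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    hidden_layers: tuple[int, ...] = (24, 16)
    use_structure: bool = True
    pixels_per_image: int = 1500
    max_iter: int = 60
    learning_rate: float = 1e-3
    batch_size: int = 512
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.feature_scales_px:
            raise ConfigError("feature_scales_px must be nonempty")
        if self.pixels_per_image <= 0:
            raise ConfigError("pixels_per_image must be positive")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError("threshold must lie in [0, 1]")


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Inference-layer settings shared by every statistical table."""

    n_boot: int = 10_000
    alpha: float = 0.05
    ssi_cutoff: float = 55.0
    n_manual_subset: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_boot < 100:
            raise ConfigError("n_boot must be >= 100")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


@dataclass
class StudyConfig:
    """Everything needed to run the full study analogue end to end."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rb: RBParams = field(default_factory=RBParams)
    ai: SegmenterConfig = field(default_factory=SegmenterConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_calibration_eyes: int = 20
    n_training_eyes: int = 50
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.rb.validate()
        self.ai.validate()
        self.analysis.validate()
        if self.n_calibration_eyes <= 0 or self.n_training_eyes <= 0:
            raise ConfigError("calibration/training eye counts must be positive")


def smoke_study_config(seed: int = 0) -> StudyConfig:
    """A desk-scale profile: small cohort, 2000 bootstrap replicates."""
    cfg = StudyConfig(seed=seed)
    cfg.cohort.n_participants = 36
    cfg.cohort.seed = seed
    cfg.analysis.n_boot = 2000
    cfg.analysis.seed = seed
    cfg.ai.seed = seed
    return cfg


def paper_profile_config(seed: int = 0) -> StudyConfig:
    """The full-inference profile: >= 10,000 bootstrap replicates, larger cohort."""
    cfg = StudyConfig(seed=seed)
    cfg.cohort.n_participants = 188  # ~1/2 of the 375-participant design
    cfg.cohort.visits_per_eye = 2
    cfg.cohort.seed = seed
    cfg.analysis.n_boot = 10_000
    cfg.analysis.seed = seed
    cfg.ai.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_CONFIG_TYPES: dict[str, type] = {
    "CohortConfig": CohortConfig,
    "RBParams": RBParams,
    "SegmenterConfig": SegmenterConfig,
    "AnalysisConfig": AnalysisConfig,
    "StudyConfig": StudyConfig,
}

_NESTED_FIELDS = {"cohort": CohortConfig, "rb": RBParams, "ai": SegmenterConfig,
                  "analysis": AnalysisConfig}


def to_dict(cfg: Any) -> dict[str, Any]:
    """Dataclass config -> plain dict (tuples become lists, enum-free)."""
    d = dataclasses.asdict(cfg)

    def _plain(obj: Any) -> Any:
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        if isinstance(obj, list):
            return [_plain(v) for v in obj]
        return obj

    return _plain(d)


def from_dict(cls: type, data: dict[str, Any]) -> Any:
    """Plain dict -> dataclass config, restoring tuple-typed fields."""
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in _NESTED_FIELDS and cls is StudyConfig:
            value = from_dict(_NESTED_FIELDS[f.name], value)
        elif isinstance(value, list):
            value = tuple(value)
        elif f.name == "severity_weights" and isinstance(value, dict):
            value = {int(k): float(v) for k, v in value.items()}
        kwargs[f.name] = value
    return cls(**kwargs)


def save_yaml(cfg: Any, path: str | Path) -> None:
    payload = {"type": type(cfg).__name__, "config": to_dict(cfg)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_yaml(path: str | Path) -> Any:
    payload = yaml.safe_load(Path(path).read_text())
    cls = _CONFIG_TYPES[payload["type"]]
    return from_dict(cls, payload["config"])
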