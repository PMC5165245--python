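"""Stage configuration dataclasses and YAML (de)serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class CrossConfig:
    """Cross-sectional (single time point) segmentation settings."""

    kappa: float = 3.0  # Mahalanobis threshold for FLAIR lesion outliers
    fill_threshold: float = 0.5  # soft-lesion level above which T1 is filled
    em_tol: float = 1e-5
    em_max_iter: int = 30
    outer_max_iter: int = 10
    outer_rel_tol: float = 0.01  # relative change in lesion voxel count
    posterior_smoothing_sigma_mm: float = 0.0  # optional smoothing, off by default


@dataclass
class PreprocessConfig:
    """Difference-image construction settings."""

    fwhm_mm: float = 30.0  # differential bias field smoothing kernel
    n_levels: int = 256  # quantile anchors for cumulative histogram matching
    analysis_threshold: float = 0.5  # WM+LES membership gate for the analysis mask


@dataclass
class JointConfig:
    """Joint two-time-point EM settings."""

    tol: float = 1e-5
    max_iter: int = 50
    prior_floor: float = 1e-3  # class priors are floored before normalization


@dataclass
class PruneConfig:
    """Lesion pruning rules."""

    posterior_threshold: float = 0.9  # binarization level (strict >)
    min_volume_ml: float = 0.005  # components below this are removed
    dilation_mm: float = 1.0  # WM-region dilation margin
    connectivity: int = 18


@dataclass
class MetricConfig:
    """Evaluation settings (lesion qualification rule)."""

    connectivity: int = 18
    min_voxels: int = 20  # qualified lesions must exceed this count (strict >)
    min_inslice: int = 5  # and reach this count in at least one slice
    slice_axis: int = 2  # axial axis of the stored orientation


@dataclass
class PipelineConfig:
    """Full longitudinal pipeline configuration."""

    cross: CrossConfig = field(default_factory=CrossConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    joint: JointConfig = field(default_factory=JointConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    convergence_tol: float = 0.01  # on (1 - Dice) of consecutive masks
    max_outer_iter: int = 10
    lesion_prior_mass: float = 0.9  # LES prior inside previous pruned mask
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            cross=CrossConfig(**raw.get("cross", {})),
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            joint=JointConfig(**raw.get("joint", {})),
            prune=PruneConfig(**raw.get("prune", {})),
            metrics=MetricConfig(**raw.get("metrics", {})),
            **{
                k: raw[k]
                for k in (
                    "convergence_tol",
                    "max_outer_iter",
                    "lesion_prior_mass",
                    "seed",
                )
                if k in raw
            },
        )
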