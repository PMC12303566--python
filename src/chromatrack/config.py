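"""Single-file pipeline configuration.

Every stage of the pipeline reads its parameters from one hierarchical
YAML document with a section per stage.  Unknown keys are rejected so a
typo in a config file fails loudly instead of silently falling back to a
default.  The document round-trips through serialization unchanged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

log = logging.getLogger("chromatrack")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class VideoConfig(_Section):
    #: typical fully-expanded chromatophore diameter in pixels; several
    #: stage defaults (DoG sigmas, LK kill threshold) are derived from it
    expected_diameter_px: float = 24.0
    #: optional region-of-interest mask file (PNG, nonzero = inside)
    roi_mask: str | None = None


class ChunkingConfig(_Section):
    #: band-pass sigmas for the difference-of-Gaussians focus score; when
    #: null they default to diameter/6 and diameter/2
    sigma_small: float | None = None
    sigma_large: float | None = None
    #: absolute focus threshold; when null a relative one is used:
    #: ``rel_focus_fraction`` times the median score of the sharpest decile
    focus_threshold: float | None = None
    rel_focus_fraction: float = 0.5
    brightness_threshold: float = 30.0
    min_chunk_length: int = 20


class SegmentationConfig(_Section):
    classifier: str = "lookup"  # lookup | random_forest | majority
    color_space: str = "RGB"  # RGB | HSV | Lab
    quantization: int = 4  # levels per channel in the lookup table
    rf_scales: tuple[float, ...] = (1.0, 2.0, 4.0)
    rf_n_estimators: int = 50
    rf_max_depth: int | None = 12
    #: remove connected components below this area (px); 0 disables
    min_component_px: int = 0


class RegistrationConfig(_Section):
    # shape filters for tracking-point candidates
    area_min_px: float = 4.0
    area_max_px: float = 2000.0
    eccentricity_max: float = 0.95
    #: small digitized disks have solidity well below 1 (a radius-3 disk
    #: is ~0.78), so the default must not reject them
    solidity_min: float = 0.7
    edge_offset_fraction: float = 0.05
    grid_cells: int = 8  # subsampling grid is grid_cells x grid_cells
    max_points_per_cell: int = 3
    # Lucas-Kanade tracker
    lk_window: int = 21
    lk_levels: int = 3
    lk_iterations: int = 10
    #: per-frame displacement above which a point is killed; when null it
    #: defaults to 0.5 * expected chromatophore diameter
    max_step_px: float | None = None
    alive_min_fraction: float = 0.5
    #: a control point is excluded from the MLS support once the mask
    #: component under it leaves this factor band around its initial
    #: area (its motion then reflects expansion, not skin; a factor of
    #: 1.2 tolerates segmentation flicker but catches the ~1 px edge
    #: motion a 10% radius change produces)
    control_area_growth_max: float = 1.2
    # moving-least-squares interpolation
    mls_grid_step: int = 8
    mls_alpha: float = 1.0  # inverse-distance weight power (w = 1/d^(2*alpha))
    mls_class: str = "affine"  # affine | similarity


class StitchingConfig(_Section):
    grid_spacing: int = 16
    patch_size: int = 64  # round-1 patch; round 2 uses half
    n_rounds: int = 2
    #: whitened-spectrum correlation peaks are diluted on soft (averaged)
    #: masterframe content; featureless patches stay below ~0.01
    peak_min: float = 0.05
    #: correspondences whose leave-one-out MLS prediction misses by more
    #: than this are discarded (patch matching can lock onto a blob that
    #: changed shape between chunks)
    max_loo_residual_px: float = 1.5
    max_reprojection_error_px: float = 2.0
    strategy: str = "chain"  # chain | all_pairs


class TerritoriesConfig(_Section):
    occupancy_min: float = 0.02
    #: minimum separation of watershed seeds when splitting merged
    #: footprints; when null defaults to half the expected diameter
    seed_min_distance_px: float | None = None


class AnisotropyConfig(_Section):
    n_slices: int = 36
    #: marker size cutoff; null = 25th percentile of mean areas
    marker_size_max_px2: float | None = None
    marker_cv_max: float = 0.1


class LongtermConfig(_Section):
    method: str = "tps"  # tps | mls
    min_jaccard: float = 0.3


class MotorUnitsConfig(_Section):
    algorithm: str = "affinity_propagation"  # affinity_propagation | hdbscan
    n_components: int | None = None  # null = per-chromatophore PCA elbow
    hdbscan_min_cluster_size: int = 2
    ap_damping: float = 0.7
    ica_max_iter: int = 500


class PipelineConfig(_Section):
    """The one configuration document for a whole dataset."""

    seed: int = 0
    log_level: str = "INFO"
    video: VideoConfig = Field(default_factory=VideoConfig)
    chunking: ChunkingConfig = Field(default_factory=ChunkingConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = Field(default_factory=RegistrationConfig)
    stitching: StitchingConfig = Field(default_factory=StitchingConfig)
    territories: TerritoriesConfig = Field(default_factory=TerritoriesConfig)
    anisotropy: AnisotropyConfig = Field(default_factory=AnisotropyConfig)
    longterm: LongtermConfig = Field(default_factory=LongtermConfig)
    motor_units: MotorUnitsConfig = Field(default_factory=MotorUnitsConfig)

    # -- derived defaults ------------------------------------------------
    def dog_sigmas(self) -> tuple[float, float]:
        d = self.video.expected_diameter_px
        s1 = self.chunking.sigma_small if self.chunking.sigma_small is not None else d / 6.0
        s2 = self.chunking.sigma_large if self.chunking.sigma_large is not None else d / 2.0
        return s1, s2

    def lk_max_step(self) -> float:
        if self.registration.max_step_px is not None:
            return self.registration.max_step_px
        return 0.5 * self.video.expected_diameter_px

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
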