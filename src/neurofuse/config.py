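"""Pipeline configuration: schema-validated YAML round-tripping.

Every tunable default of the analysis chain appears here once; unknown
keys are rejected (pydantic ``extra="forbid"``).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .eeg import EegParams
from .fnirs import FnirsParams
from .fusion import PenaltyConfig
from .simulate import DEFAULT_EEG_RATE_HZ, NoiseConfig, TruthConfig


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TruthModel(_Model):
    hb_gain: float = 0.5
    hbr_ratio: float = -0.3
    alpha_gain: float = 0.4
    latent_mean: float = 1.0
    latent_sd: float = 0.4
    target_cross_correlation: float = 0.5
    active_fnirs_rois: tuple[str, ...] = ("Left IPL", "Left SMG", "Left POCG")
    active_eeg_rois: tuple[str, ...] = ("left central", "left parietal")
    atten_fnirs: float = 0.78
    atten_eeg: float = 0.87

    def build(self) -> TruthConfig:
        return TruthConfig(**self.model_dump())


class NoiseModel(_Model):
    od_white_sd: float = 2e-3
    cardiac_amp: float = 0.05
    cardiac_freq: float = 1.1
    drift_amp: float = 5e-3
    motion_rate: float = 0.0
    motion_amp: float = 0.15
    motion_width: float = 0.4
    eeg_background_sd: float = 10.0
    eeg_alpha_amp: float = 12.0
    eeg_alpha_freq: float = 10.0
    eeg_alpha_spread_deg: float = 18.0

    def build(self) -> NoiseConfig:
        return NoiseConfig(**self.model_dump())


class SimulationModel(_Model):
    n_participants: int = 5
    eeg_rate: float = DEFAULT_EEG_RATE_HZ
    age_range: tuple[float, float] = (18.0, 65.0)
    truth: TruthModel = TruthModel()
    noise: NoiseModel = NoiseModel()


class FnirsModel(_Model):
    pca_variance_threshold: float | None = 0.9
    t_motion: float = 0.5
    t_mask: float = 1.0
    stdev_thresh: float = 20.0
    amp_thresh: float = 5.0
    spline_p: float = 0.99
    sg_window: int = 11
    band: tuple[float, float] = (0.01, 0.50)
    baseline_window: tuple[float, float] = (-5.0, 0.0)
    stim_window: tuple[float, float] = (0.0, 5.0)
    run_glm: bool = True
    outlier_n_sd: float = 2.0

    def build(self) -> FnirsParams:
        return FnirsParams(**self.model_dump())


class EegModel(_Model):
    band: tuple[float, float] = (0.3, 49.0)
    reject_z_thresh: float = 3.0
    run_ica: bool = True
    ica_n_components: int = 12
    ica_corr_thresh: float = 0.7
    ica_kurtosis_z: float = 5.0
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    csd_m: int = 4
    csd_regularization: float = 1e-5
    csd_n_legendre: int = 50
    alpha_band: tuple[float, float] = (8.0, 13.0)
    morlet_n_cycles: float = 5.0

    def build(self) -> EegParams:
        return EegParams(**self.model_dump())


class FusionModel(_Model):
    lam_lasso_eeg: float = 0.10
    lam_lasso_fnirs: float = 0.10
    lam_fused_fnirs: float = 0.05
    n_components: int = 3
    n_permutations: int = 0  # 0 disables permutation inference
    mode: str = "two_set_stacked"
    chromophore: str = "HbO"
    min_trials: int = 5
    adjacency_radius_cm: float = 3.0
    select_by_cv: bool = False

    def penalties(self) -> PenaltyConfig:
        return PenaltyConfig(
            lam_lasso_eeg=self.lam_lasso_eeg,
            lam_lasso_fnirs=self.lam_lasso_fnirs,
            lam_fused_fnirs=self.lam_fused_fnirs,
        )


class StatsModel(_Model):
    run: bool = True
    posthoc_correction: str | None = None


class PipelineConfig(_Model):
    """Everything needed to reproduce a full run from a seed."""

    seed: int = 0
    simulation: SimulationModel = SimulationModel()
    fnirs: FnirsModel = FnirsModel()
    eeg: EegModel = EegModel()
    fusion: FusionModel = FusionModel()
    stats: StatsModel = StatsModel()
    write_raw: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False))


__all__ = [
    "PipelineConfig", "SimulationModel", "TruthModel", "NoiseModel",
    "FnirsModel", "EegModel", "FusionModel", "StatsModel",
]
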