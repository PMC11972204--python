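"""Pipeline configuration: serializable parameters for a fully reproducible run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from lamiquartet.design import PerceptProcess
from lamiquartet.glm import HRFParams
from lamiquartet.synth import AcquisitionParams, CohortConfig


@dataclass
class AnalysisConfig:
    """Parameters of the analysis stages."""

    pct: float = 95.0  # winner-take-all percentile threshold
    radius: float = 0.39  # tangential cluster-extension radius (u,v units)
    highpass_cycles: float = 5.0
    min_trial_s: float = 10.0  # ERA trial-duration threshold
    window_tr: int = 5  # ERA window (offsets 0..window_tr)
    wilcoxon_mode: str = "auto"
    voxel_size_mm: float = 0.8  # for the motion QC rule (2x voxel size)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a synthetic-cohort pipeline run."""

    seed: int = 0
    scenario: str = "hypothesis2"
    n_subjects: int = 8
    hemispheres: int = 2
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.get("cohort", {})
        if isinstance(cohort, dict):
            cohort = dict(cohort)
            if isinstance(cohort.get("percept"), dict):
                cohort["percept"] = PerceptProcess(**cohort["percept"])
            if isinstance(cohort.get("acquisition"), dict):
                acq = dict(cohort["acquisition"])
                if isinstance(acq.get("hrf"), dict):
                    acq["hrf"] = HRFParams(**acq["hrf"])
                cohort["acquisition"] = AcquisitionParams(**acq)
            if isinstance(cohort.get("curvature_range"), list):
                cohort["curvature_range"] = tuple(cohort["curvature_range"])
            d["cohort"] = CohortConfig(**cohort)
        if isinstance(d.get("analysis"), dict):
            d["analysis"] = AnalysisConfig(**d["analysis"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def small_cohort_config(
    n_repetitions: int = 3,
    n_columns: int = 12,
    voxels_per_column: int = 6,
    noise_sd: float = 0.5,
) -> CohortConfig:
    """Reduced-size cohort used by simulation studies.

    Fewer super-block repetitions and shorter fixation keep runs short while
    preserving the block structure, dwell statistics and noise model.  The
    noise SD is scaled down by the variance-matching factor (~4: one
    estimation run instead of three, half the volumes per run, roughly a
    third of the cluster voxels) so that the estimation SNR of cluster-level
    quantities matches the full-size default configuration; rank-based group
    tests are scale-invariant, so null calibration is unaffected.
    """
    return CohortConfig(
        n_repetitions=n_repetitions,
        fixation_s=12.0,
        n_columns=n_columns,
        voxels_per_column=voxels_per_column,
        acquisition=AcquisitionParams(noise_sd=noise_sd),
    )
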