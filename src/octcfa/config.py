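"""Cohort-level configuration.

The defaults encode the study scale the pipeline is meant to emulate:
~414 patients with ~1.18 target lesions each, ~200 frames per lesion
(IQR 136-264) inside 540-frame pullbacks, 30.7% lesion-level TCFA
prevalence, near-zero artefact rates (median excluded fraction 0%, 90th
percentile ~3.2%), a 2-year composite event rate around 8%, and planted
hazard ratios of 2.0 (target-lesion exposure) and 5.5 (complete-segment
exposure).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class CohortConfig:
    # cohort scale
    n_patients: int = 414
    lesions_per_patient_mean: float = 1.18
    lesions_per_patient_max: int = 3
    frames_per_lesion_median: int = 200
    frames_per_lesion_iqr: Tuple[int, int] = (136, 264)
    pullback_frames: int = 540

    # frame geometry
    grid_size: int = 352
    pixel_spacing_um: float = 10.0
    n_alines: int = 504
    lumen_radius_range_px: Tuple[float, float] = (30.0, 60.0)
    lipid_thickness_px: float = 15.0
    media_thickness_px: float = 8.0

    # plaque planting
    tcfa_lesion_prevalence: float = 0.307
    extra_segment_tcfa_rate: float = 0.375
    thick_cap_fraction: float = 0.5        # of non-TCFA lesions
    borderline_arc_fraction: float = 0.3   # of non-TCFA lesions
    planted_arc_range: Tuple[float, float] = (95.0, 200.0)
    planted_cap_range: Tuple[float, float] = (35.0, 50.0)
    thick_cap_range: Tuple[float, float] = (80.0, 110.0)
    borderline_arc_range: Tuple[float, float] = (55.0, 85.0)
    plaque_len_range: Tuple[int, int] = (15, 40)

    # artefact process
    artefact_lesion_rate: float = 0.3
    artefact_frame_rate: float = 0.048
    artefact_aline_fraction_range: Tuple[float, float] = (0.26, 0.45)

    # reference-reader noise (per-lesion bias)
    reader_cap_noise_sd: float = 70.0
    reader_arc_noise_sd: float = 30.0

    # clinical follow-up
    baseline_event_rate_2y: float = 0.024
    true_hr_target_lesion: float = 2.0
    true_hr_complete_segment: float = 5.5
    admin_censor_days: float = 730.0
    admin_censor_jitter_days: float = 30.0
    event_type_probs: Tuple[float, float, float] = (0.41, 0.21, 0.38)

    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        fracs = {
            "tcfa_lesion_prevalence": self.tcfa_lesion_prevalence,
            "extra_segment_tcfa_rate": self.extra_segment_tcfa_rate,
            "thick_cap_fraction": self.thick_cap_fraction,
            "borderline_arc_fraction": self.borderline_arc_fraction,
            "artefact_lesion_rate": self.artefact_lesion_rate,
            "artefact_frame_rate": self.artefact_frame_rate,
            "baseline_event_rate_2y": self.baseline_event_rate_2y,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.thick_cap_fraction + self.borderline_arc_fraction > 1.0:
            raise ValueError("non-TCFA lesion-type fractions exceed 1")
        if self.lesions_per_patient_mean < 1:
            raise ValueError("lesions_per_patient_mean must be >= 1")
        lo, hi = self.frames_per_lesion_iqr
        if not lo <= self.frames_per_lesion_median <= hi:
            raise ValueError("frames-per-lesion IQR must bracket the median")
        if min(self.planted_cap_range) <= 0:
            raise ValueError("planted cap range must be positive")
        if self.true_hr_target_lesion <= 0 or self.true_hr_complete_segment <= 0:
            raise ValueError("hazard ratios must be positive")
        if abs(sum(self.event_type_probs) - 1.0) > 1e-9:
            raise ValueError("event_type_probs must sum to 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        # YAML-friendly: tuples become lists
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        tuple_fields = {
            f for f, v in cls.__dataclass_fields__.items()
            if "Tuple" in str(v.type)
        }
        for f in tuple_fields & set(d):
            d[f] = tuple(d[f])
        return cls(**d)
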