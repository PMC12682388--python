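"""Container types for OCT cross-sections and their derived plaque metrics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .labels import N_CLASSES


@dataclass
class SegmentationFrame:
    """One OCT cross-section as a labelled pixel grid.

    Parameters
    ----------
    labels
        2-D uint8 array of tissue class codes (0..9).
    pixel_spacing_um
        Isotropic physical pixel size in micrometres.
    n_alines
        Number of radial acquisition lines (A-lines) of the frame.
    artefact_alines
        Indices of A-lines corrupted by severe attenuation artefacts
        (blood, gas bubbles); drives the frame-exclusion rule.
    frame_index
        0-based position of the frame within its pullback.
    geometry_key
        Optional memoisation hint: frames sharing a key are guaranteed by
        their producer to have identical ``labels`` arrays, so quantification
        may be computed once and reused. ``None`` disables reuse.
    """

    labels: np.ndarray
    pixel_spacing_um: float
    n_alines: int = 504
    artefact_alines: frozenset = field(default_factory=frozenset)
    frame_index: int = 0
    geometry_key: Optional[str] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be positive")
        if self.n_alines <= 0:
            raise ValueError("n_alines must be positive")
        self.artefact_alines = frozenset(int(a) for a in self.artefact_alines)
        if self.artefact_alines and not all(
            0 <= a < self.n_alines for a in self.artefact_alines
        ):
            raise ValueError("artefact A-line indices out of range")

    @property
    def artefact_fraction(self) -> float:
        return len(self.artefact_alines) / self.n_alines

    def validate_labels(self) -> None:
        if self.labels.max(initial=0) >= N_CLASSES:
            raise ValueError("label codes must be in 0..9")


@dataclass(frozen=True)
class PlaqueMetrics:
    """Per-frame derived plaque quantities.

    ``lipid_arc_deg`` is the largest contiguous angular extent of lipid
    about the lumen centroid; ``min_cap_um`` the minimum fibrous cap
    thickness (absent when the frame shows no lipid, or when every
    lumen-lipid candidate pair is directly adjacent and therefore ignored).
    Frames failing the artefact criterion or lacking a lumen are flagged
    non-analyzable and carry no metrics.
    """

    lipid_arc_deg: float
    min_cap_um: Optional[float]
    lumen_centroid: Optional[Tuple[float, float]]
    analyzable: bool
    frame_index: int = 0
    n_inconsistent_bins: int = 0

    @classmethod
    def non_analyzable(cls, frame_index: int = 0) -> "PlaqueMetrics":
        return cls(
            lipid_arc_deg=0.0,
            min_cap_um=None,
            lumen_centroid=None,
            analyzable=False,
            frame_index=frame_index,
        )
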