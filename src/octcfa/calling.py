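"""Exclusion rules and TCFA definitions.

Rule set, with boundary conventions followed literally:

* a frame is **excluded** when strictly more than 25% of its A-lines carry
  severe artefacts;
* a lesion (or pullback) is **evaluable** when it retains at least 50% of
  its frames after frame exclusion;
* a frame **qualifies** when its lipid arc is >= 90 deg (inclusive) and its
  minimum fibrous cap thickness is < 65 um (strict);
* the AI-style unit call is positive when some window of 10 consecutive
  frames contains at least 3 qualifying frames;
* the reference-reader (core-lab) style call is positive on any single
  qualifying frame, with no window requirement;
* a patient is positive when at least one evaluable unit in scope is
  positive, irrespective of how many units the patient contributes;
  patients with no evaluable unit are dropped from that scope's analysis
  set.

By default the 10-frame window slides over *retained* frames in original
order (an excluded frame is unreadable, not evidence of plaque absence);
sliding over original frame indices instead is available via
``window_on_original_indices``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .frame import PlaqueMetrics, SegmentationFrame


@dataclass(frozen=True)
class Thresholds:
    """All rule constants in one place (defaults are the clinical standard)."""

    arc_min_deg: float = 90.0
    cap_max_um: float = 65.0
    window_frames: int = 10
    min_qualifying: int = 3
    aline_artefact_max: float = 0.25  # exclusive: frame excluded when >
    retention_min: float = 0.50  # unit evaluable when retained fraction >=
    window_on_original_indices: bool = False

    def __post_init__(self):
        if not (0 < self.aline_artefact_max < 1 and 0 < self.retention_min < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.min_qualifying > self.window_frames:
            raise ValueError("min_qualifying must be <= window_frames")


@dataclass
class TCFACall:
    """Unit-level (lesion or pullback) TCFA status with its evidence trail."""

    scope: str  # "target_lesion" or "complete_segment"
    unit_id: str
    positive: bool
    evaluable: bool
    qualifying_frames: List[int] = field(default_factory=list)
    excluded_frames: List[int] = field(default_factory=list)
    witness_window: Optional[List[int]] = None


def frame_excluded(frame: SegmentationFrame, thresholds: Thresholds) -> bool:
    """True iff the artefacted A-line fraction strictly exceeds the cutoff."""
    return len(frame.artefact_alines) / frame.n_alines > thresholds.aline_artefact_max


def unit_evaluable(excluded_flags: Sequence[bool], thresholds: Thresholds) -> bool:
    """True iff the unit retains at least ``retention_min`` of its frames."""
    flags = np.asarray(excluded_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("unit has no frames")
    retained = np.count_nonzero(~flags) / flags.size
    return bool(retained >= thresholds.retention_min)


def frame_qualifies(metrics: PlaqueMetrics, thresholds: Thresholds) -> bool:
    """Frame-level TCFA criterion; non-analyzable / lipid-free frames never qualify."""
    if not metrics.analyzable or metrics.min_cap_um is None:
        return False
    return (
        metrics.lipid_arc_deg >= thresholds.arc_min_deg
        and metrics.min_cap_um < thresholds.cap_max_um
    )


def _window_positive_batch(
    patterns: np.ndarray, window: int, min_qualifying: int
) -> np.ndarray:
    """Vectorised m-of-n caller over a batch of qualify patterns.

    ``patterns`` is (n_patterns, length) of 0/1. A unit shorter than the
    window is judged on a single window covering the whole unit.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=np.int64))
    length = patterns.shape[1]
    if length == 0:
        return np.zeros(patterns.shape[0], dtype=bool)
    cs = np.concatenate(
        [np.zeros((patterns.shape[0], 1), dtype=np.int64), patterns.cumsum(axis=1)],
        axis=1,
    )
    w = min(window, length)
    starts = np.arange(0, length - w + 1)
    window_sums = cs[:, starts + w] - cs[:, starts]
    return (window_sums >= min_qualifying).any(axis=1)


def _first_witness(qualify: np.ndarray, window: int, min_qualifying: int):
    """Indices (into the pattern) of the first window meeting the rule."""
    length = qualify.size
    w = min(window, length)
    cs = np.concatenate([[0], np.cumsum(qualify)])
    for s in range(length - w + 1):
        if cs[s + w] - cs[s] >= min_qualifying:
            return list(range(s, s + w))
    return None


def call_unit_tcfa(
    qualify_flags: Sequence[bool],
    thresholds: Thresholds,
    *,
    scope: str = "target_lesion",
    unit_id: str = "",
    excluded_flags: Optional[Sequence[bool]] = None,
    frame_indices: Optional[Sequence[int]] = None,
) -> TCFACall:
    """Apply the 3-of-10-consecutive-frames rule to one unit.

    ``qualify_flags`` covers the unit's frames in original order; frames
    marked in ``excluded_flags`` are removed before the window slides
    (default) or kept as non-qualifying placeholders when
    ``thresholds.window_on_original_indices`` is set. A non-evaluable unit
    is returned with ``evaluable=False`` and no positivity claim.
    """
    qualify = np.asarray(qualify_flags, dtype=bool)
    n = qualify.size
    if frame_indices is None:
        frame_indices = np.arange(n)
    frame_indices = np.asarray(frame_indices)
    if excluded_flags is None:
        excluded = np.zeros(n, dtype=bool)
    else:
        excluded = np.asarray(excluded_flags, dtype=bool)
    if not (qualify.size == excluded.size == frame_indices.size):
        raise ValueError("flag vectors must have equal length")

    evaluable = unit_evaluable(excluded, thresholds) if n else False
    excluded_list = [int(i) for i in frame_indices[excluded]]
    if not evaluable:
        return TCFACall(
            scope=scope,
            unit_id=unit_id,
            positive=False,
            evaluable=False,
            excluded_frames=excluded_list,
        )

    if thresholds.window_on_original_indices:
        eligible = qualify & ~excluded  # excluded frames stay, never qualify
        idx = frame_indices
    else:
        eligible = qualify[~excluded]
        idx = frame_indices[~excluded]

    positive = bool(
        _window_positive_batch(
            eligible[None, :], thresholds.window_frames, thresholds.min_qualifying
        )[0]
    )
    witness = None
    if positive:
        pos = _first_witness(
            eligible, thresholds.window_frames, thresholds.min_qualifying
        )
        witness = [int(idx[i]) for i in pos]
    return TCFACall(
        scope=scope,
        unit_id=unit_id,
        positive=positive,
        evaluable=True,
        qualifying_frames=[int(i) for i in idx[eligible]],
        excluded_frames=excluded_list,
        witness_window=witness,
    )


def call_unit_any_frame(
    qualify_flags: Sequence[bool],
    thresholds: Thresholds,
    *,
    scope: str = "target_lesion",
    unit_id: str = "",
    excluded_flags: Optional[Sequence[bool]] = None,
) -> TCFACall:
    """Reference-reader style call: positive on any single qualifying frame."""
    single = Thresholds(
        arc_min_deg=thresholds.arc_min_deg,
        cap_max_um=thresholds.cap_max_um,
        window_frames=1,
        min_qualifying=1,
        aline_artefact_max=thresholds.aline_artefact_max,
        retention_min=thresholds.retention_min,
        window_on_original_indices=thresholds.window_on_original_indices,
    )
    return call_unit_tcfa(
        qualify_flags, single, scope=scope, unit_id=unit_id,
        excluded_flags=excluded_flags,
    )


def call_patient(unit_calls: Iterable[TCFACall]) -> Optional[bool]:
    """Patient status: OR over evaluable units; ``None`` when none is evaluable.

    ``None`` means the patient is dropped from this scope's analysis set
    (no readable unit), mirroring how patients with >50% non-analyzable
    frames are handled.
    """
    evaluable = [c for c in unit_calls if c.evaluable]
    if not evaluable:
        return None
    return any(c.positive for c in evaluable)
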