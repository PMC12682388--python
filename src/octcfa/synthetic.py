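"""Synthetic OCT cohort generator.

Emulates the statistical structure of a post-MI OCT study cohort so that
every downstream stage (quantification, TCFA calling, reader agreement,
outcome analysis) can be exercised end-to-end without any imaging data:

* each patient contributes 1..3 target lesions, one pullback per lesion;
* lesions carry planted plaques with known per-frame lipid-arc and cap
  profiles, typed as TCFA (thin cap, wide arc), thick-cap fibroatheroma
  (wide arc, cap well above 65 um), borderline-arc (thin cap, arc < 90
  deg) or trace (no plaque) — the latter three never qualify as TCFA;
* a configurable fraction of patients receives one additional TCFA-grade
  plaque *outside* any target lesion, so that complete-segment TCFA
  prevalence exceeds target-lesion prevalence;
* severe A-line artefacts contaminate a small minority of frames, with
  most pullbacks entirely clean;
* a simulated core-lab reader re-reads the planted metrics under Gaussian
  per-lesion bias and applies the frame-level rule (arc >= 90 deg and cap
  < 65 um on any frame);
* 2-year follow-up times are exponential with a proportional-hazards
  effect of the planted complete-segment TCFA status, administratively
  censored at ~730 days.

Frame masks are labelled pixel grids built from concentric geometry: a
circular lumen, an intima band whose minimum radial width over the lipid
pool realises the requested cap thickness, a contiguous lipid sector
subtending the requested arc, and a media ring. Masks are deliberately
simple; see the methods note for what this does and does not emulate.

Determinism: every random draw descends from ``CohortConfig.rng_seed``;
per-pullback and per-patient substreams are derived by stable (CRC-32)
hashing of the unit id, so regenerating any one pullback is reproducible
independent of iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .calling import Thresholds, _window_positive_batch
from .config import CohortConfig
from .frame import SegmentationFrame
from .labels import BACKGROUND, INTIMA, LIPID, LUMEN, MEDIA
from .outcomes import SurvivalRecord


# --------------------------------------------------------------------------
# frame synthesis
# --------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _polar_grids(grid_size: int, qcx: int, qcy: int):
    """Radius and angle (deg, ccw from +x) of every pixel centre."""
    cx, cy = qcx / 4.0, qcy / 4.0
    y, x = np.mgrid[0:grid_size, 0:grid_size].astype(np.float32)
    r = np.hypot(x - cx, y - cy)
    theta = np.degrees(np.arctan2(y - cy, x - cx)) % 360.0
    return r, theta


def generate_frame(
    arc_deg: float,
    cap_um: float,
    lumen_radius_px: float,
    pixel_spacing_um: float = 10.0,
    aline_artefact_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    *,
    grid_size: int = 352,
    n_alines: int = 504,
    arc_start_deg: Optional[float] = None,
    lipid_thickness_px: float = 15.0,
    intima_thickness_px: Optional[float] = None,
    media_thickness_px: float = 8.0,
    centre_offset: Tuple[float, float] = (0.0, 0.0),
    frame_index: int = 0,
    geometry_key: Optional[str] = None,
) -> SegmentationFrame:
    """Construct one labelled OCT frame with a planted lipid pool.

    The lipid pool subtends ``arc_deg`` about the lumen centre and is
    separated from the lumen by an intima band of radial width
    ``cap_um`` (realised to within one pixel). ``arc_deg`` of 0 plants no
    lipid; 360 a full annulus. Raises ``ValueError`` when the requested
    geometry cannot fit inside the grid.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= arc_deg <= 360.0:
        raise ValueError("arc_deg must lie in [0, 360]")
    if cap_um < 0:
        raise ValueError("cap_um must be non-negative")
    if not 0.0 <= aline_artefact_fraction <= 1.0:
        raise ValueError("aline_artefact_fraction must lie in [0, 1]")

    cap_px = cap_um / pixel_spacing_um
    t_i = intima_thickness_px
    if t_i is None:
        t_i = max(cap_px + lipid_thickness_px + 3.0, 30.0)
    elif arc_deg > 0 and t_i < cap_px + lipid_thickness_px:
        raise ValueError("intima band too thin for the requested cap + lipid pool")

    half = (grid_size - 1) / 2.0
    outer = lumen_radius_px + t_i + media_thickness_px
    off_x, off_y = centre_offset
    if outer + max(abs(off_x), abs(off_y)) + 2.0 > half:
        raise ValueError(
            f"geometry does not fit: outer radius {outer:.1f}px exceeds grid "
            f"half-size {half:.1f}px"
        )

    # centre quantised to 1/4 px so identical geometries share cached grids
    qcx = int(round((half + off_x) * 4))
    qcy = int(round((half + off_y) * 4))
    r, theta = _polar_grids(grid_size, qcx, qcy)

    labels = np.zeros((grid_size, grid_size), dtype=np.uint8)
    labels[r <= lumen_radius_px + t_i] = INTIMA
    labels[(r > lumen_radius_px + t_i) & (r <= outer)] = MEDIA
    if arc_deg > 0:
        start = (
            float(rng.uniform(0, 360)) if arc_start_deg is None else arc_start_deg
        )
        in_sector = ((theta - start) % 360.0) < arc_deg
        if arc_deg >= 360.0:
            in_sector = np.ones_like(in_sector)
        inner = lumen_radius_px + cap_px
        lipid = in_sector & (r > inner) & (r <= inner + lipid_thickness_px)
        labels[lipid] = LIPID
    labels[r <= lumen_radius_px] = LUMEN

    n_art = int(round(aline_artefact_fraction * n_alines))
    if n_art > 0:
        start_line = int(rng.integers(0, n_alines))
        artefacts = frozenset((start_line + k) % n_alines for k in range(n_art))
    else:
        artefacts = frozenset()

    return SegmentationFrame(
        labels=labels,
        pixel_spacing_um=pixel_spacing_um,
        n_alines=n_alines,
        artefact_alines=artefacts,
        frame_index=frame_index,
        geometry_key=geometry_key,
    )


# --------------------------------------------------------------------------
# lesion and pullback specs
# --------------------------------------------------------------------------


@dataclass
class PlantedPlaque:
    """A contiguous plaque with per-frame planted metric profiles."""

    span: Tuple[int, int]  # half-open frame interval within the pullback
    arc_profile: np.ndarray  # degrees, one per frame of the span
    cap_profile: np.ndarray  # um, one per frame of the span
    arc_start_deg: float = 0.0


@dataclass
class LesionSpec:
    lesion_id: str
    pullback_id: str
    frame_span: Tuple[int, int]
    planted_plaques: List[PlantedPlaque] = field(default_factory=list)
    planted_is_tcfa: bool = False
    lesion_type: str = "trace"

    def validate(self, pullback_frames: int, thresholds: Thresholds) -> None:
        start, stop = self.frame_span
        if not (0 <= start < stop <= pullback_frames):
            raise ValueError("lesion span outside pullback bounds")
        arcs, caps = planted_profiles(self, self.frame_span)
        truth = planted_unit_truth(arcs, caps, thresholds)
        if truth != self.planted_is_tcfa:
            raise ValueError(
                f"{self.lesion_id}: planted profiles contradict planted_is_tcfa"
            )


@dataclass
class PullbackSpec:
    pullback_id: str
    patient_id: str
    n_frames: int
    lumen_radius_px: float
    lesions: List[LesionSpec] = field(default_factory=list)
    extra_plaques: List[PlantedPlaque] = field(default_factory=list)
    artefact_frame_prob: float = 0.0


@dataclass
class PatientRecord:
    patient_id: str
    lesion_ids: List[str]
    pullback_ids: List[str]
    true_tcfa_target_lesion: bool
    true_tcfa_complete_segment: bool

    def __post_init__(self):
        if not self.lesion_ids:
            raise ValueError("patients must have at least one lesion")
        if self.true_tcfa_target_lesion and not self.true_tcfa_complete_segment:
            raise ValueError(
                "target-lesion TCFA implies complete-segment TCFA "
                "(the lesion lies inside the pullback)"
            )


@dataclass
class Cohort:
    config: CohortConfig
    patients: List[PatientRecord]
    pullbacks: Dict[str, PullbackSpec]

    @property
    def lesions(self) -> Dict[str, LesionSpec]:
        out: Dict[str, LesionSpec] = {}
        for pb in self.pullbacks.values():
            for les in pb.lesions:
                out[les.lesion_id] = les
        return out


def _substream(master_seed: int, unit_id: str) -> np.random.Generator:
    """Deterministic per-unit RNG independent of generation order."""
    tag = zlib.crc32(unit_id.encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag]))


def planted_profiles(
    spec_or_pullback, span: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Planted (arc, cap) per frame over a span; NaN cap / 0 arc off-plaque."""
    start, stop = span
    n = stop - start
    arcs = np.zeros(n)
    caps = np.full(n, np.nan)
    if isinstance(spec_or_pullback, LesionSpec):
        plaques = spec_or_pullback.planted_plaques
    else:
        plaques = list(spec_or_pullback.extra_plaques)
        for les in spec_or_pullback.lesions:
            plaques = plaques + les.planted_plaques
    for pl in plaques:
        s, e = pl.span
        lo, hi = max(s, start), min(e, stop)
        if lo < hi:
            arcs[lo - start : hi - start] = pl.arc_profile[lo - s : hi - s]
            caps[lo - start : hi - start] = pl.cap_profile[lo - s : hi - s]
    return arcs, caps


def planted_frame_qualifies(
    arcs: np.ndarray, caps: np.ndarray, thresholds: Thresholds
) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (arcs >= thresholds.arc_min_deg) & (caps < thresholds.cap_max_um)


def planted_unit_truth(
    arcs: np.ndarray, caps: np.ndarray, thresholds: Thresholds
) -> bool:
    """Ground-truth TCFA status of a unit from its planted profiles."""
    q = planted_frame_qualifies(arcs, caps, thresholds)
    return bool(
        _window_positive_batch(
            q[None, :].astype(int),
            thresholds.window_frames,
            thresholds.min_qualifying,
        )[0]
    )


def _trapezoid(n: int, peak: float, edge: float, taper: int) -> np.ndarray:
    """Plateau profile with linear tapers of ``taper`` frames at each end."""
    prof = np.full(n, peak)
    for k in range(min(taper, n // 2)):
        w = (k + 1) / (taper + 1)
        prof[k] = edge + (peak - edge) * w
        prof[n - 1 - k] = edge + (peak - edge) * w
    return prof


def _make_plaque(
    span: Tuple[int, int],
    lesion_type: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> PlantedPlaque:
    n = span[1] - span[0]
    taper = min(3, max(0, (n - 5) // 2))
    if lesion_type == "tcfa":
        arc = float(rng.uniform(*config.planted_arc_range))
        cap = float(rng.uniform(*config.planted_cap_range))
    elif lesion_type == "thick_cap":
        arc = float(rng.uniform(*config.planted_arc_range))
        cap = float(rng.uniform(*config.thick_cap_range))
    elif lesion_type == "borderline_arc":
        arc = float(rng.uniform(*config.borderline_arc_range))
        cap = float(rng.uniform(*config.planted_cap_range))
    else:
        raise ValueError(f"unknown lesion type {lesion_type!r}")
    arc_profile = _trapezoid(n, arc, arc * 0.5, taper)
    cap_profile = _trapezoid(n, cap, cap + 25.0, taper)
    return PlantedPlaque(
        span=span,
        arc_profile=arc_profile,
        cap_profile=cap_profile,
        arc_start_deg=float(rng.uniform(0, 360)),
    )


def _draw_lesion_type(config: CohortConfig, rng: np.random.Generator) -> str:
    if rng.uniform() < config.tcfa_lesion_prevalence:
        return "tcfa"
    u = rng.uniform()
    if u < config.thick_cap_fraction:
        return "thick_cap"
    if u < config.thick_cap_fraction + config.borderline_arc_fraction:
        return "borderline_arc"
    return "trace"


def _frames_per_lesion(config: CohortConfig, rng: np.random.Generator) -> int:
    """Log-normal frame count matched to the configured median and IQR."""
    lo, hi = config.frames_per_lesion_iqr
    mu = np.log(config.frames_per_lesion_median)
    sigma = (np.log(hi) - np.log(lo)) / (2 * 0.6745)  # quartile z-score
    n = int(np.round(np.exp(rng.normal(mu, sigma))))
    hi_cap = max(20, config.pullback_frames - 20)
    return int(np.clip(n, min(20, hi_cap), hi_cap))


def build_lesion_spec(
    lesion_id: str,
    pullback_id: str,
    config: CohortConfig,
    rng: np.random.Generator,
    thresholds: Optional[Thresholds] = None,
    lesion_type: Optional[str] = None,
) -> LesionSpec:
    if thresholds is None:
        thresholds = Thresholds()
    if lesion_type is None:
        lesion_type = _draw_lesion_type(config, rng)
    n_frames = _frames_per_lesion(config, rng)
    start_hi = max(6, config.pullback_frames - n_frames - 5 + 1)
    start = int(rng.integers(5, start_hi))
    span = (start, start + n_frames)

    plaques: List[PlantedPlaque] = []
    if lesion_type != "trace":
        lo_len, hi_len = config.plaque_len_range
        hi_len = min(hi_len, n_frames)
        lo_len = min(lo_len, hi_len)
        plen = int(rng.integers(lo_len, hi_len + 1))
        pstart = start + int(rng.integers(0, n_frames - plen + 1))
        plaques.append(_make_plaque((pstart, pstart + plen), lesion_type, config, rng))

    spec = LesionSpec(
        lesion_id=lesion_id,
        pullback_id=pullback_id,
        frame_span=span,
        planted_plaques=plaques,
        planted_is_tcfa=(lesion_type == "tcfa"),
        lesion_type=lesion_type,
    )
    spec.validate(config.pullback_frames, thresholds)
    return spec


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------


def generate_cohort(
    config: CohortConfig, thresholds: Optional[Thresholds] = None
) -> Cohort:
    """Draw the full cohort structure (specs only — no pixel data yet)."""
    if thresholds is None:
        thresholds = Thresholds()
    patients: List[PatientRecord] = []
    pullbacks: Dict[str, PullbackSpec] = {}

    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        rng = _substream(config.rng_seed, pid)
        extra = np.random.default_rng(rng.integers(2**31)).poisson(
            config.lesions_per_patient_mean - 1.0
        )
        n_lesions = int(min(1 + extra, config.lesions_per_patient_max))

        lesion_ids, pullback_ids = [], []
        any_tcfa_target = False
        for j in range(n_lesions):
            les_id = f"{pid}-L{j}"
            pb_id = f"{pid}-PB{j}"
            les_rng = _substream(config.rng_seed, les_id)
            spec = build_lesion_spec(les_id, pb_id, config, les_rng, thresholds)
            any_tcfa_target = any_tcfa_target or spec.planted_is_tcfa
            lo, hi = config.lumen_radius_range_px
            pullbacks[pb_id] = PullbackSpec(
                pullback_id=pb_id,
                patient_id=pid,
                n_frames=config.pullback_frames,
                lumen_radius_px=float(les_rng.uniform(lo, hi)),
                lesions=[spec],
                artefact_frame_prob=(
                    float(les_rng.uniform(0, config.artefact_frame_rate))
                    if les_rng.uniform() < config.artefact_lesion_rate
                    else 0.0
                ),
            )
            lesion_ids.append(les_id)
            pullback_ids.append(pb_id)

        # complete-segment extra plaque, planted outside any lesion span
        any_tcfa_segment = any_tcfa_target
        if rng.uniform() < config.extra_segment_tcfa_rate:
            pb_id = pullback_ids[int(rng.integers(0, len(pullback_ids)))]
            pb = pullbacks[pb_id]
            placed = _plant_extra_tcfa(pb, config, rng)
            any_tcfa_segment = any_tcfa_segment or placed

        patients.append(
            PatientRecord(
                patient_id=pid,
                lesion_ids=lesion_ids,
                pullback_ids=pullback_ids,
                true_tcfa_target_lesion=any_tcfa_target,
                true_tcfa_complete_segment=any_tcfa_segment,
            )
        )
    return Cohort(config=config, patients=patients, pullbacks=pullbacks)


def _plant_extra_tcfa(
    pb: PullbackSpec, config: CohortConfig, rng: np.random.Generator
) -> bool:
    """Try to plant one TCFA-grade plaque outside the lesion span."""
    occupied = [les.frame_span for les in pb.lesions]
    plen = int(rng.integers(*config.plaque_len_range))
    gaps = []
    edges = sorted([(0, 0)] + occupied + [(pb.n_frames, pb.n_frames)])
    for (_, prev_end), (next_start, _) in zip(edges, edges[1:]):
        if next_start - prev_end >= plen + 10:
            gaps.append((prev_end + 5, next_start - 5))
    if not gaps:
        return False
    lo, hi = gaps[int(rng.integers(0, len(gaps)))]
    pstart = int(rng.integers(lo, hi - plen + 1))
    pl = _make_plaque((pstart, pstart + plen), "tcfa", config, rng)
    pb.extra_plaques.append(pl)
    return True


# --------------------------------------------------------------------------
# pullback materialisation (masks + artefact flags)
# --------------------------------------------------------------------------


@dataclass
class Pullback:
    spec: PullbackSpec
    frames: List[SegmentationFrame]

    @property
    def pullback_id(self) -> str:
        return self.spec.pullback_id


def generate_pullback(
    spec: PullbackSpec, config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> Pullback:
    """Materialise masks and artefact flags for one pullback.

    Frames outside planted plaques contain lumen/intima/media only; all
    such frames of a pullback share one label array (the lumen radius is
    held constant within a pullback) and carry a common ``geometry_key``
    so that downstream quantification can be memoised.
    """
    spans = sorted(les.frame_span for les in spec.lesions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("overlapping lesion spans")
    for s, e in spans:
        if not (0 <= s < e <= spec.n_frames):
            raise ValueError("lesion span outside pullback")

    if rng is None:
        rng = _substream(config.rng_seed, spec.pullback_id)

    arcs, caps = planted_profiles(spec, (0, spec.n_frames))
    plaque_starts = np.zeros(spec.n_frames)
    for pl in list(spec.extra_plaques) + [
        p for les in spec.lesions for p in les.planted_plaques
    ]:
        plaque_starts[pl.span[0] : pl.span[1]] = pl.arc_start_deg

    # artefact process: which frames are contaminated, and how badly
    contaminated = rng.uniform(size=spec.n_frames) < spec.artefact_frame_prob
    lo_f, hi_f = config.artefact_aline_fraction_range
    fractions = np.where(
        contaminated, rng.uniform(lo_f, hi_f, size=spec.n_frames), 0.0
    )

    base_key = f"{spec.pullback_id}:plaque-free"
    base_frame = generate_frame(
        0.0,
        0.0,
        spec.lumen_radius_px,
        config.pixel_spacing_um,
        0.0,
        rng,
        grid_size=config.grid_size,
        n_alines=config.n_alines,
        lipid_thickness_px=config.lipid_thickness_px,
        media_thickness_px=config.media_thickness_px,
        geometry_key=base_key,
    )

    frames: List[SegmentationFrame] = []
    for i in range(spec.n_frames):
        n_art = int(round(fractions[i] * config.n_alines))
        if n_art > 0:
            start_line = int(rng.integers(0, config.n_alines))
            artefacts = frozenset(
                (start_line + k) % config.n_alines for k in range(n_art)
            )
        else:
            artefacts = frozenset()
        if arcs[i] > 0:
            fr = generate_frame(
                float(arcs[i]),
                float(caps[i]),
                spec.lumen_radius_px,
                config.pixel_spacing_um,
                0.0,
                rng,
                grid_size=config.grid_size,
                n_alines=config.n_alines,
                arc_start_deg=float(plaque_starts[i]),
                lipid_thickness_px=config.lipid_thickness_px,
                media_thickness_px=config.media_thickness_px,
                frame_index=i,
            )
            fr.artefact_alines = artefacts
        else:
            fr = SegmentationFrame(
                labels=base_frame.labels,
                pixel_spacing_um=config.pixel_spacing_um,
                n_alines=config.n_alines,
                artefact_alines=artefacts,
                frame_index=i,
                geometry_key=base_key,
            )
        frames.append(fr)
    return Pullback(spec=spec, frames=frames)


def iter_pullbacks(cohort: Cohort) -> Iterator[Pullback]:
    for pb_id in sorted(cohort.pullbacks):
        yield generate_pullback(cohort.pullbacks[pb_id], cohort.config)


# --------------------------------------------------------------------------
# simulated core-lab reads
# --------------------------------------------------------------------------


def simulate_corelab_reads(
    lesion_specs: Sequence[LesionSpec],
    config: CohortConfig,
    thresholds: Optional[Thresholds] = None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, bool]:
    """Reference-reader TCFA call per lesion.

    The reader re-measures each planted frame under a per-lesion Gaussian
    bias on cap thickness and lipid arc (one draw per lesion: observer
    calibration differences act on the whole lesion, not frame-by-frame)
    and calls the lesion positive when *any* frame satisfies the
    frame-level rule (arc >= 90 deg, cap < 65 um) — no multi-frame window,
    matching how the manual reference standard is defined.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if config.reader_cap_noise_sd < 0 or config.reader_arc_noise_sd < 0:
        raise ValueError("reader noise sds must be non-negative")
    out: Dict[str, bool] = {}
    for spec in lesion_specs:
        lrng = (
            _substream(config.rng_seed, spec.lesion_id + ":reader")
            if rng is None
            else rng
        )
        eps_cap = float(lrng.normal(0.0, config.reader_cap_noise_sd))
        eps_arc = float(lrng.normal(0.0, config.reader_arc_noise_sd))
        arcs, caps = planted_profiles(spec, spec.frame_span)
        with np.errstate(invalid="ignore"):
            q = (arcs + eps_arc >= thresholds.arc_min_deg) & (
                caps + eps_cap < thresholds.cap_max_um
            )
        out[spec.lesion_id] = bool(np.any(q))
    return out


# --------------------------------------------------------------------------
# simulated clinical follow-up
# --------------------------------------------------------------------------


def simulate_survival(
    patient_ids: Sequence[str],
    exposures: Sequence[bool],
    config: CohortConfig,
    hr: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    exposures_target: Optional[Sequence[bool]] = None,
) -> List[SurvivalRecord]:
    """Exponential event times under a proportional-hazards exposure effect.

    Hazard = baseline x hr^exposure, with the baseline rate chosen so the
    2-year cumulative event probability of an unexposed patient equals
    ``baseline_event_rate_2y``. Administrative censoring at
    ``admin_censor_days`` with uniform +/- jitter; event types drawn from
    the configured death/MI/revascularisation multinomial.
    """
    if hr is None:
        hr = config.true_hr_complete_segment
    if hr <= 0:
        raise ValueError("hr must be positive")
    if not 0 < config.baseline_event_rate_2y < 1:
        raise ValueError("baseline_event_rate_2y must lie in (0, 1)")
    exposures = np.asarray(exposures, dtype=bool)
    lam0 = -np.log1p(-config.baseline_event_rate_2y) / 730.0
    records: List[SurvivalRecord] = []
    types = ["death", "mi", "revascularisation"]
    probs = np.asarray(config.event_type_probs)
    for k, pid in enumerate(patient_ids):
        prng = rng if rng is not None else _substream(config.rng_seed, pid + ":fu")
        lam = lam0 * (hr if exposures[k] else 1.0)
        t_event = float(prng.exponential(1.0 / lam))
        censor = float(
            config.admin_censor_days
            + prng.uniform(
                -config.admin_censor_jitter_days, config.admin_censor_jitter_days
            )
        )
        event = t_event <= censor
        records.append(
            SurvivalRecord(
                patient_id=pid,
                time_days=min(t_event, censor),
                event=event,
                event_type=(
                    types[int(prng.choice(3, p=probs))] if event else "none"
                ),
                exposure_target_lesion=(
                    bool(exposures_target[k]) if exposures_target is not None else None
                ),
                exposure_complete_segment=bool(exposures[k]),
            )
        )
    return records
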