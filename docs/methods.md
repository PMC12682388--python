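# Methods

`octcfa` implements the downstream half of an AI-assisted intravascular-OCT
workflow: given per-frame multi-class segmentation masks of coronary
pullbacks (we never touch raw OCT signal), it quantifies lipid plaques,
calls thin-cap fibroatheromas (TCFA), measures agreement against a manual
reference reader, and relates TCFA status to 2-year clinical outcome. A
synthetic cohort generator supplies masks, reference reads and follow-up
with the statistical structure such a study exhibits, so the entire chain
is testable without patient data.

## Frame quantification

Masks use a ten-class schema (background, guidewire artefact, lumen,
intima, media, lipid, calcium, side branch, plaque rupture, thrombus) on a
square isotropic grid, 10 µm/pixel by default.

Two per-frame quantities drive TCFA status:

* **Lipid arc** — rays are cast from the lumen centroid at the centre of
  360 half-open 1° bins and sampled at 0.4 px steps with nearest-pixel
  lookup; the arc is the largest contiguous run of lipid-positive bins,
  with wraparound across 0°. A convention choice: the *largest contiguous*
  run is reported rather than total angular coverage (the common OCT
  convention); the ray-profile object retains per-bin data so either can
  be derived.
* **Minimum fibrous cap thickness** — per lipid-positive bin, the radial
  gap between the end of the first contiguous lumen run and the first
  lipid sample, converted to µm; the reported cap is the minimum over
  bins. Candidates from directly neighbouring lumen/lipid pixels are
  ignored so that touching segmentations cannot produce spurious
  near-zero caps. Numerically this exclusion has three layers: sampled
  pixel pairs that are 8-connected, first-lipid pixels with lumen in
  their 8-neighbourhood, and measured gaps below 2 px (under
  nearest-pixel sampling a sub-2-px gap is indistinguishable from
  touching tissue). The practical floor of 20 µm on measurable caps is
  far below the 65 µm decision threshold.

Bins whose ray meets guidewire pixels before any lipid contribute no
lipid evidence (the shadowed wall is unreadable, nothing is imputed).
Bins where lipid appears radially inside the lumen boundary are counted
as inconsistent and skipped for cap measurement. Frames without lumen
pixels are non-analyzable. The ray origin is quantised to ¼ px so sample
grids can be cached across frames; the induced error is far below the
sampling step.

Error budget: nearest-pixel lookup bounds each per-bin radius by about
0.7 px (half a pixel diagonal) plus the 0.4 px step, so caps are accurate
to roughly ±1 px (±10 µm at default spacing) and arcs to ±1–2° (pixel
rasterisation at the cap radius adds up to a pixel's angular width on
each side of a pool). The test-suite verifies exact equivalence with a
naive per-bin polar-scan oracle, rotation equivariance, resolution
consistency and monotonicity.

An open measurement question is whether cap thickness should be measured
along acquisition A-lines from the catheter centre instead of rays from
the lumen centroid; the centroid convention is implemented, matching how
the measurement is defined for this pipeline.

## Exclusion rules and TCFA calling

Boundary conventions are implemented literally:

* frame excluded iff artefacted A-lines are **>25%** of all A-lines
  (strict);
* lesion/pullback evaluable iff it retains **≥50%** of frames;
* frame qualifies iff lipid arc **≥90°** (inclusive) and minimum cap
  **<65 µm** (strict);
* the AI-style unit call is positive iff some window of **10 consecutive
  frames contains ≥3 qualifying frames**; the reference-reader rule is a
  single qualifying frame with no window;
* a patient is positive iff at least one evaluable unit in scope is
  positive, irrespective of the number of units; patients with no
  evaluable unit leave that scope's analysis set.

The 10-frame window slides over *retained* frames in original order:
exclusion means "unreadable", not "plaque absent", so removed frames do
not break adjacency. The alternative (windows over original indices with
excluded frames never qualifying) is available via
`Thresholds(window_on_original_indices=True)` and covered by tests; with
realistic artefact rates (<5% of frames) the two rarely differ. The
window caller is verified against exhaustive truth-table enumeration for
all qualify patterns up to length 20.

Both analysis scopes are first-class: **target lesion** (calls per
angiographically defined lesion span) and **complete segment** (calls
over the whole pullback).

## Agreement statistics

Cohen's κ is computed from the 2×2 cross-tabulation with the
Fleiss–Cohen–Everitt asymptotic variance for its 95% CI (the common
default when no method is named); the point estimate and SE are
cross-checked against statsmodels in the tests. Sensitivity, specificity,
PPV and NPV carry exact Clopper–Pearson binomial CIs (Wilson available as
an option); Clopper–Pearson is the default because exact intervals are
the norm for small diagnostic denominators. Report rounding: percentages
to 1 dp, κ to 2 dp.

## Outcome analysis

Kaplan–Meier curves, the two-group log-rank test and univariable Cox
models come from lifelines; ties are handled by Efron's method (Breslow
would be an alternative; with near-continuous simulated times the choice
is immaterial). Monotone partial likelihoods (no events in one arm) are
reported as non-convergence rather than a divergent estimate.

The C-statistic is defined on the *binary* 2-year outcome — this is what
makes the DeLong machinery applicable, since DeLong variance applies to
AUC, not to censored concordance. For a binary marker the C-statistic
equals (sensitivity + specificity)/2. Patients censored event-free before
day 700 have unknown 2-year status and are excluded from the binary
outcome set (logged and configurable); patients with an event always
count. Paired C-statistics on the same patients are compared with the
DeLong covariance-adjusted z-test, implemented here (no installed package
provides it) and validated against a paired-bootstrap oracle.

The composite endpoint is the first of death / non-fatal MI / unplanned
revascularisation; secondary outcomes reuse the same machinery per event
type. All p-values are two-sided; significance is never used as a filter.

## Synthetic cohort generator

The generator's defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| patients | 414 | analysis-set size the pipeline targets |
| lesions/patient | 1 + Poisson(0.18), max 3 | mean 1.18 |
| frames/lesion | log-normal, median 200 | IQR ≈ (136, 264) |
| pullback frames | 540 | typical 75 mm pullback at ~0.14 mm/frame |
| grid / spacing | 352² at 10 µm | 65 µm ≈ 6.5 px resolvable |
| A-lines | 504 | standard acquisition |
| lesion TCFA prevalence | 30.7% | lesion-level positivity rate |
| extra-segment TCFA rate | 37.5% | lifts patient-level segment prevalence to ≈59% given ≈35% target-lesion prevalence |
| TCFA plaque | arc U(95, 200)°, cap U(35, 50) µm | qualifies with ≥1 px margin against measurement error |
| thick-cap plaque | arc U(95, 200)°, cap U(80, 110) µm | never qualifies (cap margin ≥1.5 px) |
| borderline-arc plaque | arc U(55, 85)°, cap U(35, 50) µm | never qualifies (arc margin ≥2 bins) |
| non-TCFA mix | 50% thick-cap / 30% borderline / 20% no plaque | gives the reader two distinct discordance routes |
| artefacts | 30% of pullbacks affected; within those, per-frame severe-contamination probability U(0, 0.048); contaminated frames have U(26%, 45%) of A-lines flagged | per-lesion excluded-frame fraction: median 0, 90th pct ≈3.2% |
| reader noise | per-lesion bias, SD 70 µm (cap), 30° (arc) | see below |
| 2-y baseline event rate | 2.4% | with the HRs below, overall rate ≈8% |
| true HR (complete segment) | 5.5 | planted exposure effect |
| censoring | 730 ± 30 days | administrative, uniform jitter |
| event types | death .41 / MI .21 / revasc .38 | first-event multinomial |

Plaques are planted as trapezoidal per-frame profiles (plateau with
3-frame tapers) over a sub-span of 15–40 frames, so TCFA lesions always
contain ≥5 consecutive qualifying frames and non-TCFA lesions none —
ground truth is unambiguous and the any-frame and 3-of-10 rules coincide
on planted profiles. Lesion spans are given (as when an angiogram
localises the target lesion), never inferred.

Survival is generated once per patient from the *complete-segment* truth:
hazard = baseline × 5.5^(segment TCFA). Because target-lesion TCFA is
nested inside segment TCFA with ≈37.5% extra-segment planting, the
marginal target-lesion hazard ratio implied by this single mechanism is
5.5 / (0.375·5.5 + 0.625) ≈ 2.0 — one coherent data-generating process
yields both effect sizes. `true_hr_target_lesion` (2.0) is used when
survival is simulated against a target-lesion exposure alone, as in the
Cox-recovery study.

**Reader model.** The simulated core lab re-measures the *planted*
profiles under one Gaussian bias per lesion on cap (SD 70 µm) and arc
(SD 30°), then applies the single-frame rule. Per-lesion (not per-frame)
bias reflects that observer calibration differences act on a whole
lesion; with per-frame noise and an any-frame rule, long lesions would
almost surely be called positive. The SDs were calibrated once so that
lesion-level agreement with the AI calls lands at κ ≈ 0.33–0.42 across
seeds, reproducing the fair-to-moderate agreement real reader pairs show;
the large cap SD is consistent with observed inter-method cap differences
of several tens of µm on discordant lesions. Both knobs are config
fields.

**Determinism.** Every draw descends from `rng_seed`; per-patient,
per-lesion and per-pullback substreams are derived by CRC-32 hashing of
the unit id, so any unit regenerates identically regardless of iteration
order. Identical seeds give byte-identical masks and tables.

**Performance.** The lumen radius is held constant within a pullback, so
all plaque-free frames of a pullback share one label array and a
`geometry_key`; the pipeline memoises quantification on that key (tests
verify memoised results equal fresh ones). A full 414-patient run
(≈264,000 frames at 352²) takes ≈90 s on one CPU.

### What the generator does and does not emulate

It emulates: the class schema and concentric vessel-wall topology;
per-frame arc/cap profiles with realistic scale; artefact sparsity;
near-threshold reader discordance; nested exposure structure and
proportional-hazards outcome at the study's effect sizes and event rate.

It does not emulate: raw OCT speckle or attenuation, eccentric or
irregular lumens (the centroid-vs-catheter distinction is therefore not
stressed), calcium/rupture/thrombus tissue, within-lesion plaque
multiplicity, lesion-level event attribution, or correlated comorbidity
structure. Passing end-to-end tests therefore demonstrates correctness of
the *rules and statistics* downstream of segmentation, not segmentation
robustness on real images.

## Degenerate inputs and numerical edge cases

* No lumen pixels → frame non-analyzable; lipid arc 0 ⇔ cap absent; if
  every cap candidate is adjacency-excluded the cap is absent while the
  arc may be positive (the frame then never qualifies).
* κ undefined (chance agreement 1) raises; pipeline reports record the
  reason instead of a value at degenerate scale.
* Cox with no events or one exposure level raises; monotone likelihood
  returns `converged=False` with a message.
* DeLong of a marker against itself reports difference 0, p = 1.
* Empty survival groups are skipped in KM report blocks.

## Problem sizes used in checks

Oracle equivalence runs on 100 random 160² frames; the window-rule
enumeration covers all 2^L patterns for L ≤ 20; Cox recovery uses 1500
simulated cohorts of n = 414 (Monte-Carlo SE of the coverage estimate
≈0.5%); log-rank power uses 300 replicates at n = 411; the end-to-end
check runs the full default configuration (414 patients). These sizes
make the Monte-Carlo error small relative to the properties being
checked while keeping a full test run to a few minutes.
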