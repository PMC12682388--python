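"""Synthetic cohort generator: masks, artefacts, reader model, follow-up."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import label as cc_label
from scipy.stats import norm

from octcfa.calling import Thresholds
from octcfa.config import CohortConfig
from octcfa.frame import SegmentationFrame
from octcfa.labels import LIPID, LUMEN, N_CLASSES
from octcfa.outcomes import kaplan_meier, logrank
from octcfa.quantify import quantify_frame
from octcfa.synthetic import (
    LesionSpec,
    PlantedPlaque,
    PullbackSpec,
    _substream,
    generate_cohort,
    generate_frame,
    generate_pullback,
    planted_profiles,
    simulate_corelab_reads,
    simulate_survival,
)

THR = Thresholds()


class TestGenerateFrame:
    def test_label_completeness_and_connected_lumen(self, rng):
        fr = generate_frame(140.0, 60.0, 45.0, 10.0, rng=rng)
        assert fr.labels.min() >= 0 and fr.labels.max() < N_CLASSES
        _, n_components = cc_label(fr.labels == LUMEN)
        assert n_components == 1

    def test_no_arc_means_no_lipid(self, rng):
        fr = generate_frame(0.0, 0.0, 45.0, 10.0, rng=rng)
        assert not (fr.labels == LIPID).any()
        assert quantify_frame(fr).lipid_arc_deg == 0.0

    def test_full_annulus(self, rng):
        fr = generate_frame(360.0, 80.0, 45.0, 10.0, rng=rng)
        assert quantify_frame(fr).lipid_arc_deg == 360.0

    def test_requested_artefact_fraction(self, rng):
        fr = generate_frame(
            0.0, 0.0, 45.0, 10.0, aline_artefact_fraction=0.3, rng=rng, n_alines=500
        )
        assert len(fr.artefact_alines) == 150

    def test_oversized_geometry_raises(self, rng):
        with pytest.raises(ValueError, match="fit"):
            generate_frame(90.0, 50.0, 160.0, 10.0, rng=rng, grid_size=352)


class TestGeneratePullback:
    def _spec(self, config, plaque=None, artefact_prob=0.0, span=(100, 300)):
        lesion = LesionSpec(
            lesion_id="L0",
            pullback_id="PB0",
            frame_span=span,
            planted_plaques=[plaque] if plaque else [],
            planted_is_tcfa=plaque is not None,
            lesion_type="tcfa" if plaque else "trace",
        )
        return PullbackSpec(
            pullback_id="PB0",
            patient_id="P0",
            n_frames=config.pullback_frames,
            lumen_radius_px=45.0,
            lesions=[lesion],
            artefact_frame_prob=artefact_prob,
        )

    def test_frame_count_and_span_metadata(self):
        cfg = CohortConfig(pullback_frames=540, grid_size=192)
        pb = generate_pullback(self._spec(cfg), cfg)
        assert len(pb.frames) == 540
        s, e = pb.spec.lesions[0].frame_span
        assert e - s == 200

    def test_zero_artefact_rate_means_no_flags(self):
        cfg = CohortConfig(pullback_frames=60, grid_size=192)
        pb = generate_pullback(self._spec(cfg, artefact_prob=0.0, span=(10, 50)), cfg)
        assert all(not f.artefact_alines for f in pb.frames)

    def test_plaque_free_frames_share_geometry(self):
        cfg = CohortConfig(pullback_frames=40, grid_size=192)
        pb = generate_pullback(self._spec(cfg, span=(5, 35)), cfg)
        keys = {f.geometry_key for f in pb.frames}
        assert keys == {"PB0:plaque-free"}
        assert all(f.labels is pb.frames[0].labels for f in pb.frames)

    def test_overlapping_spans_error(self):
        cfg = CohortConfig(pullback_frames=540, grid_size=192)
        spec = self._spec(cfg)
        spec.lesions.append(
            LesionSpec(
                lesion_id="L1", pullback_id="PB0", frame_span=(250, 400)
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_pullback(spec, cfg)

    def test_excluded_fraction_median_zero_over_200_lesions(self):
        # Monte-Carlo against the generator's own artefact settings: most
        # lesions are clean, so the median per-lesion excluded fraction is 0
        cfg = CohortConfig(n_patients=180, rng_seed=31)
        cohort = generate_cohort(cfg)
        fracs = []
        for pb_id, pb in cohort.pullbacks.items():
            r = _substream(cfg.rng_seed, pb_id)
            contaminated = r.uniform(size=pb.n_frames) < pb.artefact_frame_prob
            s, e = pb.lesions[0].frame_span
            fracs.append(contaminated[s:e].mean())
        assert len(fracs) >= 200
        assert np.median(fracs) == 0.0
        assert np.percentile(fracs, 90) < 0.08


class TestCohortStructure:
    def test_distributional_calibration(self):
        cfg = CohortConfig(n_patients=500, rng_seed=11)
        cohort = generate_cohort(cfg)
        lesions = list(cohort.lesions.values())
        assert len(lesions) >= 500
        prev = np.mean([l.planted_is_tcfa for l in lesions])
        assert abs(prev - cfg.tcfa_lesion_prevalence) < 0.05
        lengths = [l.frame_span[1] - l.frame_span[0] for l in lesions]
        lo, hi = cfg.frames_per_lesion_iqr
        assert lo <= np.median(lengths) <= hi
        per_patient = [len(p.lesion_ids) for p in cohort.patients]
        assert abs(np.mean(per_patient) - cfg.lesions_per_patient_mean) < 0.08

    def test_segment_truth_dominates_target_truth(self):
        cfg = CohortConfig(n_patients=120, rng_seed=2)
        cohort = generate_cohort(cfg)
        for p in cohort.patients:
            assert p.true_tcfa_complete_segment or not p.true_tcfa_target_lesion

    def test_lesion_specs_are_self_consistent(self):
        cfg = CohortConfig(n_patients=50, rng_seed=3)
        cohort = generate_cohort(cfg)
        for les in cohort.lesions.values():
            les.validate(cfg.pullback_frames, THR)

    def test_determinism_same_seed_identical_masks(self):
        cfg = CohortConfig(n_patients=3, rng_seed=5, pullback_frames=80, grid_size=192)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        pb_id = sorted(c1.pullbacks)[0]
        p1 = generate_pullback(c1.pullbacks[pb_id], cfg)
        p2 = generate_pullback(c2.pullbacks[pb_id], cfg)
        for f1, f2 in zip(p1.frames, p2.frames):
            assert np.array_equal(f1.labels, f2.labels)
            assert f1.artefact_alines == f2.artefact_alines


class TestCorelabReader:
    def test_zero_noise_equals_planted_truth(self):
        cfg = CohortConfig(
            n_patients=80, rng_seed=4, reader_cap_noise_sd=0.0, reader_arc_noise_sd=0.0
        )
        cohort = generate_cohort(cfg)
        reads = simulate_corelab_reads(list(cohort.lesions.values()), cfg)
        for les in cohort.lesions.values():
            assert reads[les.lesion_id] == les.planted_is_tcfa

    def test_near_threshold_frame_probability_matches_gaussian_tail(self):
        # single-frame lesions with cap pinned at 64 um, cap noise sd 20:
        # P(64 + eps < 65) = Phi(1/20) ~= 0.52
        cfg = CohortConfig(reader_cap_noise_sd=20.0, reader_arc_noise_sd=0.0, rng_seed=8)
        lesions = []
        for i in range(4000):
            pl = PlantedPlaque(
                span=(10, 11),
                arc_profile=np.array([120.0]),
                cap_profile=np.array([64.0]),
            )
            lesions.append(
                LesionSpec(
                    lesion_id=f"S{i}",
                    pullback_id=f"S{i}",
                    frame_span=(10, 11),
                    planted_plaques=[pl],
                    planted_is_tcfa=True,
                    lesion_type="tcfa",
                )
            )
        reads = simulate_corelab_reads(lesions, cfg)
        frac = np.mean(list(reads.values()))
        assert frac == pytest.approx(norm.cdf(1 / 20), abs=0.025)

    def test_kappa_lands_in_reported_band(self):
        # calibrated defaults against planted truth over >= 500 lesions
        from octcfa.agreement import build_contingency, cohen_kappa

        cfg = CohortConfig(n_patients=500, rng_seed=21)
        cohort = generate_cohort(cfg)
        lesions = list(cohort.lesions.values())
        assert len(lesions) >= 500
        reads = simulate_corelab_reads(lesions, cfg)
        ids = sorted(l.lesion_id for l in lesions)
        truth = {l.lesion_id: l.planted_is_tcfa for l in lesions}
        t = build_contingency([truth[i] for i in ids], [reads[i] for i in ids])
        assert 0.28 <= cohen_kappa(t).kappa <= 0.47


class TestSimulateSurvival:
    def test_null_hr_rejection_near_nominal(self):
        cfg = CohortConfig(baseline_event_rate_2y=0.1)
        rng = np.random.default_rng(6)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            expo = rng.uniform(size=120) < 0.5
            recs = simulate_survival(
                [f"x{i}" for i in range(120)], expo, cfg, hr=1.0, rng=rng
            )
            t = [r.time_days for r in recs]
            e = [r.event for r in recs]
            if sum(np.asarray(e)[expo]) and sum(np.asarray(e)[~expo]):
                rej += logrank(t, e, expo)[1] < 0.05
        assert 0.02 < rej / n_rep < 0.09

    def test_exposed_arm_rate_matches_closed_form(self):
        # baseline 2-y rate 6.3%, HR 1.99 -> exposed rate 1-(1-.063)^1.99 ~ 12%
        cfg = CohortConfig(
            baseline_event_rate_2y=0.063, admin_censor_jitter_days=0.0
        )
        rng = np.random.default_rng(9)
        n = 40000
        recs = simulate_survival(
            [f"x{i}" for i in range(n)], np.ones(n, bool), cfg, hr=1.99, rng=rng
        )
        frac = np.mean([r.event for r in recs])
        expected = 1 - (1 - 0.063) ** 1.99
        assert frac == pytest.approx(expected, abs=0.006)
        assert expected == pytest.approx(0.12, abs=0.01)

    def test_immediate_censoring_gives_flat_km(self):
        cfg = CohortConfig(admin_censor_days=0.0, admin_censor_jitter_days=0.0)
        recs = simulate_survival(
            ["a", "b", "c"], [True, False, True], cfg, rng=np.random.default_rng(1)
        )
        assert all(not r.event and r.time_days == 0.0 for r in recs)
        km = kaplan_meier([r.time_days for r in recs], [r.event for r in recs])
        assert np.all(km["survival"].to_numpy() == 1.0)

    def test_event_types_only_for_events(self):
        cfg = CohortConfig(baseline_event_rate_2y=0.3)
        recs = simulate_survival(
            [f"x{i}" for i in range(300)],
            np.zeros(300, bool),
            cfg,
            rng=np.random.default_rng(10),
        )
        for r in recs:
            assert (r.event_type == "none") == (not r.event)
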