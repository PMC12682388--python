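#!/usr/bin/env python
"""Generate a small demonstration cohort and write example pullback masks.

Produces, under results/demo/: two multi-frame TIFF pullbacks with sidecar
JSON metadata (pixel spacing, A-line count, artefact A-lines, lesion
spans), plus the cohort structure tables. Downstream scripts consume these
files, mimicking how externally produced segmentation masks would enter
the pipeline.
"""

from pathlib import Path

import pandas as pd

from octcfa import io as oio
from octcfa.config import CohortConfig
from octcfa.synthetic import generate_cohort, generate_pullback

OUT = Path(__file__).resolve().parents[1] / "results" / "demo"


def demo_config() -> CohortConfig:
    # reduced scale so masks stay small; geometry identical to defaults
    return CohortConfig(
        n_patients=8,
        rng_seed=2024,
        pullback_frames=120,
        frames_per_lesion_median=50,
        frames_per_lesion_iqr=(35, 70),
        plaque_len_range=(12, 25),
        baseline_event_rate_2y=0.15,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = demo_config()
    cohort = generate_cohort(cfg)
    cfg.to_yaml(OUT / "config.yaml")

    rows = [
        {
            "patient_id": p.patient_id,
            "n_lesions": len(p.lesion_ids),
            "true_tcfa_target": p.true_tcfa_target_lesion,
            "true_tcfa_segment": p.true_tcfa_complete_segment,
        }
        for p in cohort.patients
    ]
    pd.DataFrame(rows).to_csv(OUT / "patients.csv", index=False)

    for pb_id in sorted(cohort.pullbacks)[:2]:
        pb = generate_pullback(cohort.pullbacks[pb_id], cfg)
        spans = {l.lesion_id: l.frame_span for l in pb.spec.lesions}
        oio.write_pullback(pb.frames, OUT / f"{pb_id}.tif", spans)
        print(f"wrote {pb_id}.tif ({len(pb.frames)} frames, spans {spans})")

    n_tcfa = sum(l.planted_is_tcfa for l in cohort.lesions.values())
    print(
        f"cohort: {len(cohort.patients)} patients, {len(cohort.lesions)} lesions, "
        f"{n_tcfa} with a planted TCFA"
    )


if __name__ == "__main__":
    main()
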