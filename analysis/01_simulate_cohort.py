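#!/usr/bin/env python
"""Generate the synthetic longitudinal matched-pair cohort and the
cross-sectional external validation cohort.

The discovery cohort emulates a prospective matched case-control design:
50 AD case/control pairs, up to three blood draws spanning -16 to +7 years
around clinical onset, EPIC-style beta-values built from a six-cell-type
blood mixture with planted stable, interaction, crossover, aging and clock
CpG effects.  The external cohort is larger, cross-sectional, with a
different sex ratio and APOE e4 enrichment and attenuated planted effects.

Writes results/cohort/* and prints the design summary.
"""

import json
from pathlib import Path

import numpy as np

from methylpanel import io
from methylpanel.simulate import (
    CohortConfig, DemographicShift, generate_cohort, generate_external_cohort,
)

OUT = Path("results/cohort")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=SEED)
    matrix, sheet, truth = generate_cohort(config)

    external_matrix, external_sheet = generate_external_cohort(
        config, truth, n_controls=324, n_cases=146,
        shift=DemographicShift(), attenuation=0.5)

    io.write_beta_matrix(matrix, OUT / "beta.tsv.gz",
                         detection_path=OUT / "detp.tsv.gz")
    matrix.design.rename_axis("probe_id").to_frame().to_csv(OUT / "design.csv")
    io.write_sample_sheet(sheet, OUT / "samples.csv")
    truth.to_json(OUT / "truth.json")
    io.write_beta_matrix(external_matrix, OUT / "external_beta.tsv.gz")
    io.write_sample_sheet(external_sheet, OUT / "external_samples.csv")
    with open(OUT / "config.json", "w") as fh:
        json.dump({k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()}, fh, indent=2)

    n_visits = sheet.groupby("subject_id").size()
    print(f"discovery cohort: {sheet.subject_id.nunique()} subjects "
          f"({(sheet.ad == 1).sum()} case samples) in "
          f"{sheet.pair_id.nunique()} matched pairs, "
          f"{len(sheet)} samples, {matrix.n_probes} CpGs")
    print(f"visits per subject: {dict(n_visits.value_counts().sort_index())}")
    print(f"time to onset range: [{sheet.time.min():.1f}, "
          f"{sheet.time.max():.1f}] years; onset ages "
          f"{sheet.onset_age.min():.0f}-{sheet.onset_age.max():.0f}")
    print("planted CpG classes:",
          dict(truth.probe_class.value_counts().sort_index()))
    print(f"external cohort: {len(external_sheet)} subjects "
          f"({(external_sheet.ad == 1).sum()} AD cases), "
          f"e4 carriage {external_sheet.query('ad==1').apoe_e4.mean():.0%} "
          f"cases vs {external_sheet.query('ad==0').apoe_e4.mean():.0%} controls")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
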