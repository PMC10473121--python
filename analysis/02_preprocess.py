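#!/usr/bin/env python
"""QC and normalization of the discovery beta matrix.

Detection-failed entries (p > 0.05) are masked to missing, blacklisted
probes removed, the two probe-design classes aligned by beta-mixture
quantile normalization, and probes with any remaining missing value dropped
so the probe-wise analyses see a complete matrix.

Reads results/cohort/, writes results/preprocess/.
"""

import json
from pathlib import Path

import numpy as np

from methylpanel import io
from methylpanel.preprocess import (
    ProbeBlacklists, bmiq_normalize, drop_incomplete_probes, filter_probes,
    mask_low_quality,
)

IN = Path("results/cohort")
OUT = Path("results/preprocess")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = io.read_beta_matrix(IN / "beta.tsv.gz",
                                 detection_path=IN / "detp.tsv.gz",
                                 design_path=IN / "design.csv")
    print(f"input: {matrix.n_probes} CpGs x {matrix.n_samples} samples")

    masked = mask_low_quality(matrix, threshold=0.05)
    n_masked = int(np.isnan(masked.values.to_numpy()).sum())
    print(f"masked {n_masked} entries with detection p > 0.05")

    # blacklists are user-supplied in real use; here a demonstration set of
    # ten probes standing in for sex-chromosome exclusions
    blacklist = ProbeBlacklists(sex_chromosome=set(matrix.probes[-10:]))
    filtered, filter_report = filter_probes(masked, blacklist)
    print(f"blacklist filtering: {filter_report.n_in} -> {filter_report.n_out} "
          f"(removed {filter_report.n_removed}; per set {filter_report.detail})")

    normalized = bmiq_normalize(filtered)
    shift = np.nanmedian(np.abs(normalized.values.to_numpy()
                                - filtered.values.to_numpy()))
    print(f"beta-mixture quantile normalization: median |shift| = {shift:.4f}")

    complete, drop_report = drop_incomplete_probes(normalized)
    print(f"complete-case probes: {drop_report.n_in} -> {drop_report.n_out} "
          f"(dropped {drop_report.n_removed} with any missing value)")

    io.write_beta_matrix(complete, OUT / "beta_clean.tsv.gz")
    with open(OUT / "qc_report.json", "w") as fh:
        json.dump({
            "n_probes_in": matrix.n_probes,
            "n_entries_masked": n_masked,
            "blacklist_removed": filter_report.n_removed,
            "blacklist_detail": filter_report.detail,
            "median_normalization_shift": float(shift),
            "incomplete_probes_dropped": drop_report.n_removed,
            "n_probes_out": drop_report.n_out,
        }, fh, indent=2)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
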