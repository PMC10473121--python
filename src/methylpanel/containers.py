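"""Core data containers shared across the pipeline.

The array's native measure is the beta-value: the methylation fraction of a
CpG site, in [0, 1].  A study is represented by a :class:`BetaMatrix`
(CpG probes x samples) plus a *sample sheet*, a plain :class:`pandas.DataFrame`
with one row per blood sample.  Sample-sheet columns used by the pipeline:

========== ==================================================================
column      meaning
========== ==================================================================
sample_id   unique sample identifier (matrix column name)
subject_id  donor identifier (repeated across longitudinal visits)
pair_id     matched case-control pair identifier (subjects nest in pairs)
ad          1 = Alzheimer's case, 0 = matched control
sex         "F" / "M"
age         chronological age at blood sampling, years
onset_age   age at clinical AD onset (controls inherit their matched case's)
time        years to/after AD onset at sampling (age - onset_age)
apoe_e4     1 = carries at least one APOE e4 allele
smoker      1 = ever reported smoking
rtl         relative leukocyte telomere length (T/S ratio, unitless)
========== ==================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "subject_id", "pair_id", "ad", "sex", "age",
    "onset_age", "time", "apoe_e4", "smoker", "rtl",
]


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta-values.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with one column per sample.  Missing
        measurements are ``NaN``; observed entries lie in [0, 1].
    detection_p
        Optional per-entry detection p-value channel, same shape as
        ``values``.
    design
        Optional per-probe Illumina design class ("I" or "II"), used by the
        beta-mixture quantile normalization.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    design: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe IDs in beta matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in beta matrix")
        vals = self.values.to_numpy()
        observed = vals[~np.isnan(vals)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise ValueError("detection_p shape does not match values")
        if self.design is not None and not self.design.index.equals(self.values.index):
            self.design = self.design.reindex(self.values.index)

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        """Return a new matrix restricted to (and ordered by) ``probe_ids``."""
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.probes)
        if len(missing):
            raise KeyError(f"probes not in matrix: {list(missing[:5])}")
        return BetaMatrix(
            values=self.values.loc[idx],
            detection_p=None if self.detection_p is None else self.detection_p.loc[idx],
            design=None if self.design is None else self.design.loc[idx],
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
            design=None if self.design is None else self.design.copy(),
        )


@dataclass
class PanelDefinition:
    """A set of CpGs with association directions, forming a composite score.

    ``signs`` maps probe ID -> +1/-1 (direction of association with AD);
    ``weights`` optionally maps probe ID -> the mixed-model AD coefficient,
    used by the weighted score variant.
    """

    probes: list[str]
    signs: dict[str, int]
    weights: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("duplicate probes in panel")
        for p in self.probes:
            if self.signs.get(p) not in (-1, 1):
                raise ValueError(f"panel probe {p} must have sign +1 or -1")

    def __len__(self) -> int:
        return len(self.probes)


def validate_sample_sheet(sheet: pd.DataFrame, require: tuple[str, ...] = ()) -> None:
    """Raise if mandatory sample-sheet columns are absent."""
    needed = {"sample_id"} | set(require)
    missing = needed.difference(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
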