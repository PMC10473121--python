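"""Coefficient-table-driven linear epigenetic clocks and delta ages.

An epigenetic clock is a linear model over CpG beta-values: a latent score
``intercept + sum_i w_i * beta_i`` passed through a calibration transform.
Age-estimating clocks report years; pace-style clocks (e.g. rate-of-aging
scores) are unitless and skip the delta-age step.  Delta age — clock age
minus chronological age — is the working measure of epigenetic age
acceleration here, since age-residual approaches assume independent
observations, which repeated longitudinal samples violate.

Published coefficient tables are not bundled; the CSV schema (probe_id,
weight plus a JSON sidecar) accepts them verbatim.  A toy clock matched to
the synthetic cohort generator is available via :func:`toy_clock`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .preprocess import knn_impute

logger = logging.getLogger(__name__)


@dataclass
class ClockDefinition:
    """A linear epigenetic clock: intercept, CpG weights, calibration."""

    name: str
    intercept: float
    weights: dict[str, float]
    calibration: str = "identity"       # "identity" | "piecewise_log"
    adult_age: float = 20.0             # anchor of the piecewise-log transform
    is_age_estimator: bool = True

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("clock needs at least one CpG weight")
        if not np.isfinite(self.intercept) or not np.isfinite(self.adult_age):
            raise ValueError("calibration parameters must be finite")
        if self.calibration not in ("identity", "piecewise_log"):
            raise ValueError(f"unknown calibration '{self.calibration}'")
        if not self.is_age_estimator and self.calibration != "identity":
            raise ValueError("pace clocks use identity calibration")

    def calibrate(self, latent: np.ndarray) -> np.ndarray:
        if self.calibration == "identity":
            return latent
        # standard adult-age-anchored inverse transform: exponential growth
        # in childhood, linear in adulthood, continuous at latent 0
        a = self.adult_age
        latent = np.asarray(latent, dtype=float)
        return np.where(latent < 0,
                        (1 + a) * np.exp(latent) - 1,
                        (1 + a) * latent + a)


def compute_clock(m: BetaMatrix, clock: ClockDefinition, sheet: pd.DataFrame,
                  allow_missing: bool = False, k: int = 10) -> pd.DataFrame:
    """Evaluate a clock on every sample.

    Returns a table with columns (sample_id, clock, clock_value, age,
    delta).  ``delta`` is filled by :func:`delta_age` for age-estimating
    clocks and left missing for pace clocks.  With ``allow_missing``,
    absent or missing clock CpGs are KNN-imputed first and the count logged
    (arrays routinely lack a handful of a clock's training CpGs).
    """
    wanted = pd.Index(clock.weights.keys())
    present = wanted.intersection(m.probes)
    if len(present) == 0:
        raise ValueError(f"no CpGs of clock '{clock.name}' present in matrix")
    n_absent = len(wanted) - len(present)
    sub = m.subset_probes(present)
    has_nan = bool(np.isnan(sub.values.to_numpy()).any())
    if n_absent or has_nan:
        if not allow_missing:
            raise ValueError(
                f"clock '{clock.name}': {n_absent} CpGs absent and/or missing "
                "values present; pass allow_missing=True to impute")
        logger.info("clock %s: %d absent CpGs; imputing missing values",
                    clock.name, n_absent)
        if has_nan:
            sub = knn_impute(sub, k=min(k, m.n_samples - 1))
    w = np.array([clock.weights[p] for p in sub.probes])
    latent = clock.intercept + w @ sub.values.to_numpy()
    value = clock.calibrate(latent)
    ages = sheet.set_index("sample_id").loc[sub.samples, "age"].to_numpy()
    res = pd.DataFrame({
        "sample_id": sub.samples,
        "clock": clock.name,
        "clock_value": value,
        "age": ages,
        "delta": np.nan,
    })
    if clock.is_age_estimator:
        res = delta_age(res)
    return res


def delta_age(result: pd.DataFrame, is_age_estimator: bool = True) -> pd.DataFrame:
    """Fill delta = clock value - chronological age.

    Pace clocks are passed through unchanged (their raw value is the
    measure) with a warning.
    """
    out = result.copy()
    if not is_age_estimator:
        logger.warning("delta_age called on a pace clock; raw values kept")
        return out
    out["delta"] = out["clock_value"] - out["age"]
    return out


def replace_low_outliers(values: pd.Series) -> pd.Series:
    """Replace values below mean - 3 SD by the second-lowest original value.

    The cutoff uses the mean and (sample) SD of the input; "second lowest"
    is the second-lowest *distinct* original value, so tied minima are all
    replaced by the same number.  Idempotent: replacement values are never
    below the recomputed cutoff in practice, and a second application uses
    the post-replacement statistics.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    x = values.astype(float)
    cutoff = x.mean() - 3 * x.std(ddof=1)
    low = x < cutoff
    if not low.any():
        return x.copy()
    distinct = np.sort(x.unique())
    if len(distinct) < 2:
        return x.copy()
    out = x.copy()
    out[low] = distinct[1]
    return out


def toy_clock(truth, name: str = "toy_linear") -> ClockDefinition:
    """Build the clock matched to a synthetic cohort's clock CpGs.

    The generator encodes chronological age linearly in its clock CpGs:
    ``beta_c = intercept_c + slope_c * (age - anchor)``.  Averaging the
    per-CpG inversions gives ``age = b0 + sum_c beta_c / (K * slope_c)``,
    a plain linear clock with identity calibration.
    """
    k = len(truth.clock_slope)
    if k == 0:
        raise ValueError("ground truth has no clock CpGs")
    weights = {p: 1.0 / (k * s) for p, s in truth.clock_slope.items()}
    intercept = truth.clock_anchor_age - sum(
        truth.clock_intercept[p] * w for p, w in weights.items())
    return ClockDefinition(name=name, intercept=float(intercept),
                           weights=weights, calibration="identity",
                           is_age_estimator=True)
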