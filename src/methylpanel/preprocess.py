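"""Probe-level QC, filtering, normalization and imputation.

The QC path mirrors standard EPIC-array practice: entries with detection
p-value above 0.05 are masked to missing, probes on user-supplied blacklists
(multimapping, SNP-proximal, meQTL, sex-chromosome) are removed, probes with
any remaining missing value are dropped for the probe-wise analyses, and the
two Illumina probe-design classes are aligned per sample by a beta-mixture
quantile normalization.  K-nearest-neighbour imputation fills missing values
where a complete matrix is not required (e.g. before clock estimation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix

logger = logging.getLogger(__name__)


@dataclass
class ProbeBlacklists:
    """Named probe-ID exclusion sets; sets may overlap."""

    multimapping: set[str] = field(default_factory=set)
    snp_proximal: set[str] = field(default_factory=set)
    meqtl: set[str] = field(default_factory=set)
    sex_chromosome: set[str] = field(default_factory=set)

    def union(self) -> set[str]:
        return self.multimapping | self.snp_proximal | self.meqtl | self.sex_chromosome


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step: in - removed = out."""

    n_in: int
    n_removed: int
    n_out: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_in - self.n_removed == self.n_out


def mask_low_quality(m: BetaMatrix, threshold: float = 0.05) -> BetaMatrix:
    """Set entries with detection p strictly greater than ``threshold`` missing."""
    if m.detection_p is None:
        raise ValueError("beta matrix has no detection p-value channel")
    out = m.copy()
    failed = out.detection_p.to_numpy() > threshold
    vals = out.values.to_numpy(copy=True)
    vals[failed] = np.nan
    out.values = pd.DataFrame(vals, index=m.probes, columns=m.samples)
    return out


def filter_probes(m: BetaMatrix, bl: ProbeBlacklists) -> tuple[BetaMatrix, FilterReport]:
    """Remove the union of the blacklist sets; unknown IDs are ignored."""
    union = bl.union()
    present = m.probes.intersection(union)
    unknown = union.difference(m.probes)
    if unknown:
        logger.warning("%d blacklisted probe IDs not present in matrix", len(unknown))
    keep = m.probes.difference(present)
    keep = m.probes[m.probes.isin(keep)]  # preserve original order
    out = m.subset_probes(keep)
    detail = {
        "multimapping": len(m.probes.intersection(bl.multimapping)),
        "snp_proximal": len(m.probes.intersection(bl.snp_proximal)),
        "meqtl": len(m.probes.intersection(bl.meqtl)),
        "sex_chromosome": len(m.probes.intersection(bl.sex_chromosome)),
    }
    report = FilterReport(n_in=m.n_probes, n_removed=len(present),
                          n_out=out.n_probes, detail=detail)
    return out, report


def drop_incomplete_probes(m: BetaMatrix) -> tuple[BetaMatrix, FilterReport]:
    """Drop every probe with at least one missing beta-value."""
    complete = ~m.values.isna().any(axis=1)
    out = m.subset_probes(m.probes[complete])
    return out, FilterReport(n_in=m.n_probes,
                             n_removed=int((~complete).sum()),
                             n_out=out.n_probes)


def drop_failed_samples(m: BetaMatrix, failed_ids) -> tuple[BetaMatrix, FilterReport]:
    """Remove samples flagged by array-level QC (identity mismatch etc.)."""
    failed = m.samples.intersection(pd.Index(failed_ids))
    keep = m.samples.difference(failed)
    keep = m.samples[m.samples.isin(keep)]
    out = BetaMatrix(
        values=m.values[keep],
        detection_p=None if m.detection_p is None else m.detection_p[keep],
        design=m.design,
    )
    return out, FilterReport(n_in=m.n_samples, n_removed=len(failed),
                             n_out=out.n_samples)


# ---------------------------------------------------------------------------
# beta-mixture quantile normalization

def _fit_beta_mixture(x: np.ndarray, max_iter: int = 100,
                      tol: float = 1e-4) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM fit of a 3-component beta mixture (unmethylated / hemi / methylated).

    Returns (weights, a, b) for the three components ordered by mean.
    """
    x = np.clip(x, 1e-6, 1 - 1e-6)
    # moment-based init from tertile split
    q = np.quantile(x, [1 / 3, 2 / 3])
    groups = [x[x <= q[0]], x[(x > q[0]) & (x <= q[1])], x[x > q[1]]]
    a = np.empty(3)
    b = np.empty(3)
    w = np.array([len(g) for g in groups], dtype=float)
    w /= w.sum()
    for i, g in enumerate(groups):
        mu, var = g.mean(), max(g.var(), 1e-4)
        nu = max(mu * (1 - mu) / var - 1, 0.5)
        a[i], b[i] = max(mu * nu, 0.05), max((1 - mu) * nu, 0.05)
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = np.stack([w[i] * stats.beta.pdf(x, a[i], b[i]) for i in range(3)])
        tot = dens.sum(axis=0)
        tot[tot <= 0] = 1e-300
        resp = dens / tot
        ll = np.log(tot).sum()
        w = resp.mean(axis=1)
        for i in range(3):
            r = resp[i]
            rs = r.sum()
            if rs < 1e-8:
                continue
            mu = (r * x).sum() / rs
            var = (r * (x - mu) ** 2).sum() / rs
            var = min(max(var, 1e-5), mu * (1 - mu) * 0.999)
            nu = mu * (1 - mu) / var - 1
            a[i], b[i] = max(mu * nu, 0.05), max((1 - mu) * nu, 0.05)
        if abs(ll - ll_old) < tol * (1 + abs(ll_old)):
            break
        ll_old = ll
    order = np.argsort(a / (a + b))
    return w[order], a[order], b[order]


def _state_assign(x: np.ndarray, w, a, b) -> np.ndarray:
    dens = np.stack([w[i] * stats.beta.pdf(np.clip(x, 1e-6, 1 - 1e-6), a[i], b[i])
                     for i in range(3)])
    return dens.argmax(axis=0)


def bmiq_normalize(m: BetaMatrix, max_iter: int = 100) -> BetaMatrix:
    """Beta-mixture quantile normalization of design class II onto class I.

    Per sample, a 3-state beta mixture is fitted by EM to each design class;
    class-II values are mapped within each state through the class-II CDF and
    the class-I inverse CDF, so the two chemistries share a common scale.
    Probes of design class I are untouched, hence rank order within each
    design class is preserved.  Samples where EM degenerates fall back to
    identity with a warning.
    """
    if m.design is None:
        raise ValueError("per-probe design class required for normalization")
    out = m.copy()
    design = m.design.to_numpy()
    is2 = design == "II"
    if not is2.any() or is2.all():
        return out  # single design class: nothing to map
    vals = out.values.to_numpy(copy=True)
    for j in range(m.n_samples):
        x1 = vals[~is2, j]
        x2 = vals[is2, j]
        ok1, ok2 = ~np.isnan(x1), ~np.isnan(x2)
        if ok1.sum() < 30 or ok2.sum() < 30:
            logger.warning("sample %s: too few probes per design class, skipped",
                           m.samples[j])
            continue
        try:
            w1, a1, b1 = _fit_beta_mixture(x1[ok1], max_iter=max_iter)
            w2, a2, b2 = _fit_beta_mixture(x2[ok2], max_iter=max_iter)
        except Exception:  # EM failure: identity fallback
            logger.warning("sample %s: mixture EM failed, identity fallback",
                           m.samples[j])
            continue
        x2o = x2[ok2]
        states = _state_assign(x2o, w2, a2, b2)
        mapped = x2o.copy()
        for s in range(3):
            sel = states == s
            if not sel.any():
                continue
            u = stats.beta.cdf(np.clip(x2o[sel], 1e-6, 1 - 1e-6), a2[s], b2[s])
            u = np.clip(u, 1e-9, 1 - 1e-9)
            mapped[sel] = stats.beta.ppf(u, a1[s], b1[s])
        x2[ok2] = np.clip(mapped, 0.0, 1.0)
        vals[is2, j] = x2
    out.values = pd.DataFrame(vals, index=m.probes, columns=m.samples)
    return out


def knn_impute(m: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute missing beta-values from the k nearest samples.

    Nearness is Euclidean distance over mutually complete probes; each
    missing entry becomes the inverse-distance-weighted mean of the k
    nearest samples observed at that probe.
    """
    vals = m.values.to_numpy(copy=True)
    missing = np.isnan(vals)
    if not missing.any():
        return m.copy()
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = m.probes[all_missing][0]
        raise ValueError(f"probe {bad} is missing in every sample")
    if m.n_samples < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples for k={k}")
    n = m.n_samples
    # pairwise distances over mutually observed probes
    dist = np.zeros((n, n))
    obs = ~missing
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[:, i] & obs[:, j]
            if not both.any():
                dist[i, j] = dist[j, i] = np.inf
                continue
            d = vals[both, i] - vals[both, j]
            dist[i, j] = dist[j, i] = np.sqrt((d * d).mean())
    for j in range(n):
        rows = np.flatnonzero(missing[:, j])
        if rows.size == 0:
            continue
        order = np.argsort(dist[j])
        order = order[order != j]
        for r in rows:
            donors = [o for o in order if obs[r, o]][:k]
            w = 1.0 / (dist[j, donors] + 1e-9)
            vals[r, j] = float(np.average(vals[r, donors], weights=w))
    out = m.copy()
    out.values = pd.DataFrame(np.clip(vals, 0, 1), index=m.probes, columns=m.samples)
    return out
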