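"""CpG-wise longitudinal scan and the signed-sum longitudinal AD panel.

Each probe's beta-value is regressed on AD status, time to/after onset,
their interaction, and covariates, with nested random intercepts for
subject within matched pair (see :mod:`methylpanel.lmm`).  Probes enter
the panel when the AD main effect is significant at the exploratory
threshold (p < 0.001 by default), its magnitude is at least 0.05 on the
beta scale (a 5% case-control methylation difference), and the fitted
case-control difference keeps the same sign at the earliest and latest
observed times (no crossover interaction).  The panel score of a sample is
the sum of its beta-values at the selected probes, each multiplied by +/-1
according to the direction of association — or by the mixed-model AD
coefficient in the weighted variant.

Because no probe is expected to survive FDR correction in a cohort of this
size, Benjamini-Hochberg q-values are always computed and reported next to
the exploratory selection, and the genomic inflation factor lambda is
reported as a scan-level sanity check.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, PanelDefinition
from .lmm import LmmSpec, NestedLmmDesign, build_design

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["estimate", "se", "z", "p", "q", "estimate_interaction",
                "p_interaction", "diff_at_tmin", "diff_at_tmax",
                "converged", "singular", "error"]


def ewas_scan(m: BetaMatrix, sheet: pd.DataFrame, spec: LmmSpec,
              granulocyte: pd.Series | None = None,
              progress_every: int = 1000) -> pd.DataFrame:
    """Fit the mixed model to every probe.

    Returns one row per probe with the AD-term estimate/SE/p, the
    interaction term, BH q-values, and the fitted case-control difference
    evaluated at the earliest and latest observed times (used by the
    crossover exclusion).  Per-probe failures are recorded in the ``error``
    column and the scan continues.
    """
    if np.isnan(m.values.to_numpy()).any():
        raise ValueError("scan requires a complete matrix; run preprocessing first")
    X, names = build_design(sheet, spec, granulocyte)
    if "ad" not in names:
        raise ValueError("the scan needs the AD term in the model")
    design = NestedLmmDesign(X, sheet["pair_id"].to_numpy(),
                             sheet["subject_id"].to_numpy(), names)
    tname = spec.time_scale
    iname = f"ad:{tname}"
    tvals = sheet[tname].to_numpy(dtype=float)
    tmin, tmax = float(tvals.min()), float(tvals.max())

    vals = m.values.to_numpy()
    rows = []
    for i, probe in enumerate(m.probes):
        if progress_every and i and i % progress_every == 0:
            logger.info("scan: %d/%d probes", i, m.n_probes)
        y = vals[i]
        if np.ptp(y) == 0.0:
            rows.append({c: np.nan for c in SCAN_COLUMNS}
                        | {"converged": False, "singular": False,
                           "error": "zero variance"})
            continue
        try:
            r = design.fit(y)
        except Exception as exc:  # keep scanning
            rows.append({c: np.nan for c in SCAN_COLUMNS}
                        | {"converged": False, "singular": False,
                           "error": str(exc)})
            continue
        b_ad = r.params["ad"]
        b_int = r.params.get(iname, 0.0)
        rows.append({
            "estimate": b_ad,
            "se": r.se["ad"],
            "z": r.zvalues["ad"],
            "p": r.pvalues["ad"],
            "q": np.nan,
            "estimate_interaction": b_int,
            "p_interaction": r.pvalues.get(iname, np.nan),
            "diff_at_tmin": b_ad + b_int * tmin,
            "diff_at_tmax": b_ad + b_int * tmax,
            "converged": r.converged,
            "singular": r.singular,
            "error": "",
        })
    out = pd.DataFrame(rows, index=m.probes, columns=SCAN_COLUMNS)
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("scan: %d probes failed or were skipped", n_failed)
    return out


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor: median observed chi^2 over the null median.

    lambda = median(qchisq_1(1 - p)) / 0.4549364, the median of the
    chi-square distribution with one degree of freedom.  Values near 1
    indicate no systematic inflation of the test statistics.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        logger.warning("genomic lambda on %d p-values is unstable", p.size)
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_panel(results: pd.DataFrame, p_thresh: float = 0.001,
                 effect_thresh: float = 0.05) -> PanelDefinition:
    """Apply the composite selection rule to a scan result table.

    A probe is selected when (i) the AD term has p < ``p_thresh``, (ii) the
    AD estimate magnitude is >= ``effect_thresh`` on the beta scale, and
    (iii) the fitted case-control difference has the same sign at the
    earliest and latest observed times (the crossover exclusion).  Signs
    come from the AD estimate; weights are the AD estimates themselves.
    """
    needed = {"estimate", "p", "diff_at_tmin", "diff_at_tmax"}
    if not needed.issubset(results.columns):
        raise ValueError(f"scan results missing columns {needed - set(results.columns)}")
    r = results.dropna(subset=["estimate", "p"])
    keep = (
        (r["p"] < p_thresh)
        & (r["estimate"].abs() >= effect_thresh)
        & (np.sign(r["diff_at_tmin"]) == np.sign(r["diff_at_tmax"]))
        & (r["diff_at_tmin"] != 0)
    )
    sel = r.index[keep]
    if len(sel) == 0:
        logger.warning("panel selection is empty at p<%g, |effect|>=%g",
                       p_thresh, effect_thresh)
    signs = {p: int(np.sign(r.loc[p, "estimate"])) for p in sel}
    weights = {p: float(r.loc[p, "estimate"]) for p in sel}
    return PanelDefinition(
        probes=list(sel), signs=signs, weights=weights,
        metadata={"p_thresh": p_thresh, "effect_thresh": effect_thresh},
    )


def panel_score(m: BetaMatrix, panel: PanelDefinition,
                weighted: bool = False) -> pd.Series:
    """Signed-sum panel score per sample: sum_i sign_i * beta_i.

    With ``weighted`` the +/-1 signs are replaced by the mixed-model AD
    coefficients stored in the panel.
    """
    missing = [p for p in panel.probes if p not in m.probes]
    if missing:
        raise KeyError(f"panel probes absent from matrix: {missing}")
    if len(panel) == 0:
        return pd.Series(0.0, index=m.samples, name="panel_score")
    sub = m.values.loc[panel.probes]
    if weighted:
        if not panel.weights:
            raise ValueError("panel has no weights")
        w = np.array([panel.weights[p] for p in panel.probes])
    else:
        w = np.array([panel.signs[p] for p in panel.probes], dtype=float)
    return pd.Series(w @ sub.to_numpy(), index=m.samples, name="panel_score")
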