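"""REML engine for the two-level nested random-intercept Gaussian model.

The longitudinal design is matched case-control pairs with repeated visits:
observations correlate within a subject and, more weakly, within a matched
pair.  The model is

    y = X beta + u_pair + v_subject + e,
    u ~ N(0, s2_pair), v ~ N(0, s2_subject), e ~ N(0, s2_resid),

with subjects nested within pairs.  The marginal covariance is block
diagonal by pair, with blocks of at most a few visits per subject, which
this solver exploits: the residual variance is profiled out and the REML
criterion is optimized over the two variance *ratios* (pair and subject
variance relative to residual), with per-pair Cholesky factors shared
between pairs that have the same visit pattern.  An epigenome-wide scan
re-fits the same design against thousands of probe responses, so the
design-side bookkeeping is precomputed once in :class:`NestedLmmDesign`.

Fixed-effect inference is by Wald z-test (normal reference); with ~200+
observations per fit the normal approximation is standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats


@dataclass
class LmmResult:
    """Fixed effects with Wald inference plus variance components."""

    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    vc_pair: float
    vc_subject: float
    vc_residual: float
    converged: bool
    singular: bool          # a variance component pinned at zero
    n_obs: int
    loglike: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.se,
            "z": self.zvalues, "p": self.pvalues,
        })


class NestedLmmDesign:
    """Precomputed design for repeated REML fits with varying response.

    Parameters
    ----------
    X
        (n_obs, p) fixed-effects design matrix.
    pair, subject
        length-n_obs grouping labels; subjects must nest within pairs.
    names
        fixed-effect term names (length p).
    """

    def __init__(self, X: np.ndarray, pair, subject, names: list[str]):
        X = np.asarray(X, dtype=float)
        pair = np.asarray(pair)
        subject = np.asarray(subject)
        n = X.shape[0]
        if len(pair) != n or len(subject) != n:
            raise ValueError("grouping vectors must match design rows")
        # nesting check: each subject appears in exactly one pair
        sub_pair = pd.DataFrame({"s": subject, "g": pair}).drop_duplicates()
        if sub_pair["s"].duplicated().any():
            raise ValueError("subjects are not nested within pairs")
        # sort observations by (pair, subject) so blocks are contiguous
        order = np.lexsort((subject, pair))
        self.order = order
        self.X = X[order]
        self.names = list(names)
        self.n, self.p = X.shape
        pair_s, subject_s = pair[order], subject[order]

        # group pairs by their subject-size pattern so the per-block
        # Cholesky is computed once per pattern and applied in a batch
        self.patterns: list[dict] = []
        by_pattern: dict[tuple, list[np.ndarray]] = {}
        start = 0
        for g, cnt in zip(*np.unique(pair_s, return_counts=True)):
            idx = np.arange(start, start + cnt)
            assert (pair_s[idx] == g).all()
            start += cnt
            _, sizes = np.unique(subject_s[idx], return_counts=True)
            by_pattern.setdefault(tuple(sizes), []).append(idx)
        for sizes, idx_list in by_pattern.items():
            ng = sum(sizes)
            zs = np.zeros((ng, len(sizes)))
            pos = 0
            for k, sz in enumerate(sizes):
                zs[pos:pos + sz, k] = 1.0
                pos += sz
            idx = np.stack(idx_list)                       # (m, ng)
            self.patterns.append({
                "sizes": sizes,
                "J": np.ones((ng, ng)),
                "S": zs @ zs.T,                            # subject block mask
                "idx": idx,
                "Xg": self.X[idx],                         # (m, ng, p)
            })

    # -- REML pieces -------------------------------------------------------

    def _profiled(self, theta: np.ndarray, y: np.ndarray):
        """Return (A, c, yWy, logdetW) for W = I + tp*J + ts*S per block."""
        tp, ts = theta
        p = self.p
        A = np.zeros((p, p))
        c = np.zeros(p)
        yWy = 0.0
        logdetW = 0.0
        for pat in self.patterns:
            ng = pat["J"].shape[0]
            W = np.eye(ng) + tp * pat["J"] + ts * pat["S"]
            L = linalg.cholesky(W, lower=True)
            logdetW += 2.0 * np.log(np.diag(L)).sum() * pat["idx"].shape[0]
            Xg = pat["Xg"]                                  # (m, ng, p)
            yg = y[pat["idx"]]                              # (m, ng)
            m = Xg.shape[0]
            flat = np.concatenate(
                [Xg.transpose(1, 0, 2).reshape(ng, m * p),
                 yg.T], axis=1)
            sol = linalg.cho_solve((L, True), flat)
            WiX = sol[:, :m * p].reshape(ng, m, p).transpose(1, 0, 2)
            Wiy = sol[:, m * p:].T                          # (m, ng)
            A += np.einsum("mip,miq->pq", Xg, WiX)
            c += np.einsum("mip,mi->p", Xg, Wiy)
            yWy += float(np.einsum("mi,mi->", yg, Wiy))
        return A, c, yWy, logdetW

    def _neg2_reml(self, theta: np.ndarray, y: np.ndarray) -> float:
        A, c, yWy, logdetW = self._profiled(theta, y)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, c)
        q = yWy - c @ beta
        if q <= 0:
            return np.inf
        return logdetW + logdetA + (self.n - self.p) * np.log(q)

    def fit(self, y: np.ndarray, fix_theta: tuple[float, float] | None = None,
            starts: tuple = ((0.2, 0.5),)) -> LmmResult:
        """REML fit for one response vector.

        ``fix_theta`` clamps the (pair, subject) variance ratios — e.g.
        ``(0, 0)`` reduces the fit to ordinary least squares.
        """
        y = np.asarray(y, dtype=float)[self.order]
        converged = True
        if fix_theta is not None:
            theta = np.asarray(fix_theta, dtype=float)
        else:
            best = None
            for x0 in starts:
                res = optimize.minimize(
                    lambda u: self._neg2_reml(np.exp(u) - 1e-8, y),
                    np.log(np.asarray(x0) + 1e-8),
                    method="Nelder-Mead",
                    options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 300},
                )
                if best is None or res.fun < best.fun:
                    best = res
            converged = bool(best.success) or np.isfinite(best.fun)
            theta = np.clip(np.exp(best.x) - 1e-8, 0.0, None)
            theta[theta < 1e-7] = 0.0   # pin boundary solutions
        singular = bool((theta == 0).any()) if fix_theta is None else False

        A, c, yWy, logdetW = self._profiled(theta, y)
        beta = np.linalg.solve(A, c)
        q = yWy - c @ beta
        sigma2 = q / (self.n - self.p)
        cov = sigma2 * np.linalg.inv(A)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.diag(cov))
            z = beta / se
            pvals = 2.0 * stats.norm.sf(np.abs(z))
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * (logdetW + logdetA + (self.n - self.p) * (np.log(sigma2) + 1)
                     + (self.n - self.p) * np.log(2 * np.pi))
        idx = pd.Index(self.names)
        return LmmResult(
            params=pd.Series(beta, index=idx),
            se=pd.Series(se, index=idx),
            zvalues=pd.Series(z, index=idx),
            pvalues=pd.Series(np.clip(pvals, np.finfo(float).tiny, 1.0), index=idx),
            vc_pair=float(theta[0] * sigma2),
            vc_subject=float(theta[1] * sigma2),
            vc_residual=float(sigma2),
            converged=converged,
            singular=singular,
            n_obs=self.n,
            loglike=float(ll),
        )


@dataclass
class LmmSpec:
    """Which fixed terms enter the model and on which time scale.

    ``time_scale`` is "time" (years to/after AD onset) or "age"
    (chronological age at sampling).  The AD-by-time interaction requires
    both main effects.
    """

    response: str = "beta"
    include_ad: bool = True
    include_time: bool = True
    include_interaction: bool = True
    include_apoe: bool = True
    include_smoking: bool = True
    include_granulocyte: bool = True
    time_scale: str = "time"

    def __post_init__(self) -> None:
        if self.include_interaction and not (self.include_ad and self.include_time):
            raise ValueError("AD x time interaction requires both main effects")
        if self.time_scale not in ("time", "age"):
            raise ValueError("time_scale must be 'time' or 'age'")


def build_design(sheet: pd.DataFrame, spec: LmmSpec,
                 granulocyte: pd.Series | None = None) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix from a sample sheet.

    ``granulocyte`` maps sample_id -> granulocyte proportion; required when
    the spec includes that covariate.
    """
    cols = [np.ones(len(sheet))]
    names = ["intercept"]
    t = sheet[spec.time_scale].to_numpy(dtype=float)
    if spec.include_ad:
        cols.append(sheet["ad"].to_numpy(dtype=float))
        names.append("ad")
    if spec.include_time:
        cols.append(t)
        names.append(spec.time_scale)
    if spec.include_interaction:
        cols.append(sheet["ad"].to_numpy(dtype=float) * t)
        names.append(f"ad:{spec.time_scale}")
    if spec.include_apoe:
        cols.append(sheet["apoe_e4"].to_numpy(dtype=float))
        names.append("apoe_e4")
    if spec.include_smoking:
        cols.append(sheet["smoker"].to_numpy(dtype=float))
        names.append("smoker")
    if spec.include_granulocyte:
        if granulocyte is None:
            raise ValueError("spec includes granulocyte but none supplied")
        g = granulocyte.reindex(sheet["sample_id"]).to_numpy(dtype=float)
        if np.isnan(g).any():
            raise ValueError("granulocyte proportion missing for some samples")
        cols.append(g)
        names.append("granulocyte")
    if (time_in := t).min() == time_in.max() and spec.include_time:
        raise ValueError("time has no variation")
    return np.column_stack(cols), names


def fit_lmm(sheet: pd.DataFrame, y: np.ndarray, spec: LmmSpec,
            granulocyte: pd.Series | None = None,
            fix_theta: tuple[float, float] | None = None) -> LmmResult:
    """Fit the nested mixed model for one response.

    Convenience wrapper building the design from the sample sheet; for
    probe-wise scans use :class:`NestedLmmDesign` directly and reuse it.
    """
    if sheet.groupby("pair_id")["subject_id"].nunique().min() < 1:
        raise ValueError("each pair needs at least one subject")
    X, names = build_design(sheet, spec, granulocyte)
    design = NestedLmmDesign(X, sheet["pair_id"].to_numpy(),
                             sheet["subject_id"].to_numpy(), names)
    return design.fit(np.asarray(y, dtype=float), fix_theta=fix_theta)
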