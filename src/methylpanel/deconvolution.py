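"""Reference-based blood-cell deconvolution by constrained projection.

Bulk blood methylation is modelled as a convex mixture of purified
cell-type profiles: for each sample, the observed beta vector over the
reference CpGs is projected onto the reference columns under
nonnegativity and a sum-to-one equality constraint.  The resulting six
fractions (granulocytes, CD8+ T, CD4+ T, NK, B, monocytes) serve as model
covariates; the granulocyte fraction, the dominant component of blood, is
the one carried into the mixed models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import BetaMatrix


def _project_sample(y: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Minimize ||ref @ p - y||^2 s.t. p >= 0, sum(p) = 1."""
    k = ref.shape[1]
    A = ref.T @ ref
    b = ref.T @ y

    def obj(p):
        return 0.5 * p @ A @ p - b @ p

    def grad(p):
        return A @ p - b

    res = optimize.minimize(
        obj, np.full(k, 1.0 / k), jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                      "jac": lambda p: np.ones(k)}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    p = np.clip(res.x, 0.0, None)
    return p / p.sum()


def estimate_proportions(m: BetaMatrix, ref: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell-type proportions for every sample.

    Parameters
    ----------
    m
        Beta matrix containing (at least) the reference CpGs.
    ref
        CpG x cell-type reference of mean beta-values per purified type.

    Returns
    -------
    DataFrame of shape (samples, cell types); rows sum to 1.
    """
    shared = m.probes.intersection(ref.index)
    if len(shared) < ref.shape[1]:
        raise ValueError(
            f"only {len(shared)} reference CpGs present; need >= {ref.shape[1]}")
    R = ref.loc[shared].to_numpy()
    if np.linalg.matrix_rank(R) < ref.shape[1]:
        raise ValueError("reference matrix is rank deficient; "
                         "cell types are not identifiable")
    vals = m.values.loc[shared].to_numpy()
    if np.isnan(vals).any():
        raise ValueError("deconvolution requires complete beta values; impute first")
    out = np.empty((m.n_samples, ref.shape[1]))
    for j in range(m.n_samples):
        out[j] = _project_sample(vals[:, j], R)
    return pd.DataFrame(out, index=m.samples, columns=ref.columns)


def granulocyte_covariate(props: pd.DataFrame, zscore: bool = False,
                          column: str = "granulocyte") -> pd.Series:
    """Per-sample granulocyte fraction, optionally z-scored across samples."""
    if column not in props.columns:
        raise ValueError(f"no '{column}' column in proportions table")
    g = props[column].astype(float)
    if zscore:
        sd = g.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError("zero variance in granulocyte proportion")
        g = (g - g.mean()) / sd
    return g
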