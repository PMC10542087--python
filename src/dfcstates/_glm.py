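"""Vectorised ordinary-least-squares group contrasts.

One design matrix, many responses: the group-difference t statistic of the
model ``y ~ group + covariates`` is computed simultaneously for every edge
or node.  Identical (to numerical precision) to fitting each response with a
general OLS routine; used where thousands of fits per permutation are needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

GROUP_COLUMN = "group"
PATIENT, CONTROL = "patient", "control"


def encode_design(meta: pd.DataFrame, covariates=()) -> tuple:
    """Build the design matrix [intercept, group, covariates...].

    ``group`` is coded patient=1, control=0, so a positive contrast means
    patient > control.  ``sex`` (M/F) is coded M=1, F=0.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    n = len(meta)
    cols = {"intercept": np.ones(n), "group": (meta[GROUP_COLUMN] == PATIENT).to_numpy(float)}
    for cov in covariates:
        v = meta[cov]
        if v.dtype == object:
            vals = sorted(v.dropna().unique())
            if set(vals) <= {"M", "F"}:
                cols[cov] = (v == "M").to_numpy(float)
            else:
                raise ValueError(f"cannot encode non-numeric covariate '{cov}'")
        else:
            cols[cov] = v.to_numpy(float)
    x = np.column_stack(list(cols.values()))
    if not np.isfinite(x).all():
        raise ValueError("design matrix contains missing values")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear columns among {_collinear(x, list(cols))}"
        )
    return x, list(cols)


def _collinear(x: np.ndarray, names: list) -> list:
    """Name columns involved in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(x, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    dropped = [names[piv[i]] for i in range(len(names)) if i >= len(diag) or diag[i] <= tol]
    # report the dropped column(s) plus whatever they duplicate
    return dropped or names


def group_t(x: np.ndarray, y: np.ndarray, coef_idx: int = 1) -> tuple:
    """t statistic and two-sided p of one coefficient for every column of y.

    Parameters
    ----------
    x : ndarray, shape (n, p)
    y : ndarray, shape (n, m)
    coef_idx : index of the tested coefficient (default: the group column).

    Returns
    -------
    (t, p, df) with t, p of shape (m,).
    """
    n, p = x.shape
    df = n - p
    if df < 1:
        raise ValueError("not enough observations for the design")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_idx, coef_idx], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[coef_idx] / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pval, df
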