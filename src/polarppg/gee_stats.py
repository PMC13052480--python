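"""Linear GEE of perfusion index on skin tone, polarization and their
interaction, with cluster-robust (sandwich) inference.

Model and estimation
--------------------
For participant (cluster) ``i`` with outcome vector ``y_i`` and design
``X_i`` (columns: intercept, ITA, cross-polarized indicator, ITA x cross),
the marginal mean is ``mu_i = X_i beta`` (identity link, Gaussian
variance).  Coefficients solve the estimating equations by Fisher scoring:

    beta <- beta + (sum_i X_i' V_i^-1 X_i)^-1  sum_i X_i' V_i^-1 (y_i - X_i beta)

with working covariance ``V_i = phi * R_i(alpha)``.  The scale ``phi`` and
the exchangeable correlation ``alpha`` are refreshed each iteration by the
standard moment estimators (denominators corrected by the parameter count,
matching the conventional reference formulas, so fixed points coincide with
established implementations).  Uncertainty comes from the sandwich

    cov(beta) = B^-1 M B^-1,  B = sum X_i'V_i^-1 X_i,
    M = sum X_i'V_i^-1 r_i r_i' V_i^-1 X_i,

which is consistent even when the working correlation is wrong.  Wald
statistics are (estimate/SE)^2 against chi-square(1); CIs are z-based,
estimate +/- 1.96 SE, with no small-sample degree-of-freedom correction.
Under the independence working correlation the estimating equations reduce
to the normal equations, so the point estimates are exactly OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

COEF_NAMES = ("Intercept", "ITA", "Cross-polarized", "ITA*Cross-polarized")

Z_95 = 1.96  # z-based CI half-width multiplier


class RankDeficiencyError(ValueError):
    """Design matrix is not full rank (e.g. one condition entirely absent)."""


class ConvergenceError(RuntimeError):
    """Fisher scoring failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: List[np.ndarray]):
        super().__init__(message)
        self.trace = trace


@dataclass
class GEEFit:
    """Fitted GEE: estimates, sandwich SEs, z CIs, Wald tests."""

    names: Tuple[str, ...]
    params: np.ndarray
    sandwich_se: np.ndarray
    ci95: np.ndarray  # shape (p, 2)
    wald: np.ndarray
    p: np.ndarray
    working_correlation: str
    alpha_hat: float
    phi_hat: float
    n_clusters: int
    n_obs: int
    n_iter: int
    cov: np.ndarray = None  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        """Numeric coefficient table (one row per coefficient)."""
        return pd.DataFrame(
            {
                "name": list(self.names),
                "estimate": self.params,
                "se": self.sandwich_se,
                "ci_lower": self.ci95[:, 0],
                "ci_upper": self.ci95[:, 1],
                "wald": self.wald,
                "p": self.p,
            }
        )


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Check the long-format PI table invariants."""
    required = {"participant_id", "wavelength_nm", "condition", "segment", "pi", "ita_deg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if (table["pi"] < 0).any():
        raise ValueError("pi values must be >= 0")
    keys = table[["participant_id", "wavelength_nm", "condition", "segment"]]
    if keys.duplicated().any():
        raise ValueError("duplicated (participant, wavelength, condition, segment) rows")
    per_pid = table.groupby("participant_id")["ita_deg"].nunique()
    if (per_pid > 1).any():
        raise ValueError("ita_deg must be constant within participant")


def build_design(
    table: pd.DataFrame, wavelength: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix for one wavelength's model.

    Columns: [1, ita, cross indicator, ita*cross]; co-polarized is the
    reference level.  Returns ``(y, X, cluster_ids)`` with rows ordered as
    in the table.  Participants observed under a single condition are kept
    (with a warning); a table with no cross-polarized rows at all cannot
    identify the condition terms and raises :class:`RankDeficiencyError`.
    """
    validate_cohort_table(table)
    sub = table[table["wavelength_nm"] == wavelength]
    if sub.empty:
        raise ValueError(f"no rows for wavelength {wavelength}")
    y = sub["pi"].to_numpy(dtype=float)
    ita = sub["ita_deg"].to_numpy(dtype=float)
    cross = (sub["condition"] == "cross").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), ita, cross, ita * cross])
    cluster_ids = sub["participant_id"].to_numpy()
    one_condition = (
        sub.groupby("participant_id")["condition"].nunique().loc[lambda s: s < 2]
    )
    if len(one_condition):
        warnings.warn(
            f"participants with a single condition retained: {list(one_condition.index)}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            "design is rank deficient (are both polarization conditions present?)"
        )
    return y, X, cluster_ids


def _cluster_slices(cluster_ids: np.ndarray) -> List[np.ndarray]:
    order = pd.unique(cluster_ids)
    return [np.flatnonzero(cluster_ids == cid) for cid in order]


def _exchangeable_alpha(
    resid: np.ndarray, groups: List[np.ndarray], n_params: int
) -> Tuple[float, float]:
    """Moment estimators (phi, alpha) for the exchangeable structure."""
    n_obs = len(resid)
    phi = float(resid @ resid) / (n_obs - n_params)
    pair_sum = 0.0
    n_pairs = 0.0
    for idx in groups:
        r = resid[idx]
        pair_sum += (r.sum() ** 2 - r @ r) / 2.0
        m = len(idx)
        n_pairs += 0.5 * m * (m - 1)
    if n_pairs <= n_params:
        return phi, 0.0
    alpha = (pair_sum / phi) / (n_pairs - n_params)
    return phi, alpha


def _solve_exchangeable(R_alpha: float, block: np.ndarray) -> np.ndarray:
    """Return R(alpha)^-1 @ block for an exchangeable correlation matrix,
    using the closed form R^-1 = [I - a/(1+(m-1)a) J] / (1-a)."""
    m = block.shape[0]
    a = R_alpha
    col_sums = block.sum(axis=0, keepdims=True)
    return (block - (a / (1.0 + (m - 1) * a)) * col_sums) / (1.0 - a)


def fit_gee(
    y: np.ndarray,
    X: np.ndarray,
    cluster_ids: np.ndarray,
    working_correlation: str = "exchangeable",
    maxiter: int = 100,
    tol: float = 1e-10,
    names: Sequence[str] = COEF_NAMES,
) -> GEEFit:
    """Fit the linear GEE with identity link and Gaussian variance.

    ``working_correlation`` is ``independence`` or ``exchangeable``.
    Convergence is declared when ``max |delta beta| < tol``; failure raises
    :class:`ConvergenceError` with the iteration trace.  An estimated
    exchangeable correlation with ``|alpha| >= 1`` is clamped (with a
    warning) to keep the working matrix positive definite.
    """
    if working_correlation not in ("independence", "exchangeable"):
        raise ValueError("working_correlation must be independence|exchangeable")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_obs, n_params = X.shape
    if np.linalg.matrix_rank(X) < n_params:
        raise RankDeficiencyError("X is rank deficient")
    groups = _cluster_slices(np.asarray(cluster_ids))
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    max_group = max(len(g) for g in groups)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    trace = [beta.copy()]
    alpha = 0.0
    phi = 1.0
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        resid = y - X @ beta
        if working_correlation == "exchangeable":
            phi, alpha = _exchangeable_alpha(resid, groups, n_params)
            upper = 0.999
            lower = -0.999 / max(1, max_group - 1)
            if alpha >= 1.0 or alpha <= -1.0 / max(1, max_group - 1):
                warnings.warn(f"estimated alpha {alpha:.4f} clamped")
                alpha = float(np.clip(alpha, lower, upper))
        else:
            phi = float(resid @ resid) / (n_obs - n_params)
            alpha = 0.0
        B = np.zeros((n_params, n_params))
        u = np.zeros(n_params)
        for idx in groups:
            Xi, ri = X[idx], resid[idx]
            if working_correlation == "exchangeable":
                RinvX = _solve_exchangeable(alpha, Xi)
                Rinvr = _solve_exchangeable(alpha, ri[:, None])[:, 0]
            else:
                RinvX, Rinvr = Xi, ri
            B += Xi.T @ RinvX
            u += Xi.T @ Rinvr
        delta = np.linalg.solve(B, u)
        beta = beta + delta
        trace.append(beta.copy())
        if np.max(np.abs(delta)) < tol:
            break
    else:
        raise ConvergenceError(
            f"GEE did not converge in {maxiter} iterations", trace
        )

    # final moment estimates and sandwich at the converged beta
    resid = y - X @ beta
    if working_correlation == "exchangeable":
        phi, alpha = _exchangeable_alpha(resid, groups, n_params)
        alpha = float(np.clip(alpha, -0.999 / max(1, max_group - 1), 0.999))
    else:
        phi = float(resid @ resid) / (n_obs - n_params)
        alpha = 0.0
    B = np.zeros((n_params, n_params))
    M = np.zeros((n_params, n_params))
    for idx in groups:
        Xi, ri = X[idx], resid[idx]
        if working_correlation == "exchangeable":
            RinvX = _solve_exchangeable(alpha, Xi)
            Rinvr = _solve_exchangeable(alpha, ri[:, None])[:, 0]
        else:
            RinvX, Rinvr = Xi, ri
        B += Xi.T @ RinvX
        s = Xi.T @ Rinvr
        M += np.outer(s, s)
    Binv = np.linalg.inv(B)
    cov = Binv @ M @ Binv  # phi cancels between B and M
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    ci = np.column_stack([beta - Z_95 * se, beta + Z_95 * se])
    return GEEFit(
        names=tuple(names),
        params=beta,
        sandwich_se=se,
        ci95=ci,
        wald=wald,
        p=pvals,
        working_correlation=working_correlation,
        alpha_hat=float(alpha),
        phi_hat=float(phi),
        n_clusters=len(groups),
        n_obs=n_obs,
        n_iter=n_iter,
        cov=cov,
    )


def wald_table(fit: GEEFit) -> pd.DataFrame:
    """Formatted per-coefficient report table (strings, report precision)."""
    from .signal_io import format_coefficient_table

    return format_coefficient_table(fit.to_frame())


def ols_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Closed-form OLS coefficients (oracle for the independence GEE)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
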